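"""Daily particle-release schedule from a kelp raster and seasonal curve.

Particles are released daily over a calendar year.  The number released
each day follows the seasonal detrital-production curve (a monthly step
function; production peaks in autumn and stays elevated through late
winter), and release positions are drawn from the kelp-occurrence
probability raster — cells are chosen with probability proportional to
their kelp probability, and the position is uniform within the chosen
cell.  A particle is an equal quantum of detritus; all mass weighting
happens through the daily counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BathymetryGrid

__all__ = [
    "DEFAULT_PRODUCTION_CURVE",
    "ReleaseSchedule",
    "seasonal_weights",
    "sample_positions",
    "build_schedule",
]

#: relative monthly detrital production (Jan..Dec, southern hemisphere):
#: low through summer, rising in March, peaking March-May, elevated through
#: August, tapering through spring.
DEFAULT_PRODUCTION_CURVE = (0.4, 0.4, 1.0, 1.0, 1.0, 0.8, 0.8, 0.7,
                            0.4, 0.3, 0.3, 0.3)


@dataclass(frozen=True)
class ReleaseSchedule:
    """Per-day release counts and positions.

    ``dates`` is a daily :class:`pandas.DatetimeIndex`, ``counts`` the
    particles released each day (summing exactly to ``total``), and
    ``positions`` one ``(count, 2)`` array of (x, y) points per day, each
    on a cell with positive kelp probability.
    """

    dates: pd.DatetimeIndex
    counts: np.ndarray
    positions: list[np.ndarray]
    total: int
    seed: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.total:
            raise ValueError("daily counts must sum to the total budget")
        if any(p.shape != (c, 2) for p, c in zip(self.positions, self.counts)):
            raise ValueError("positions and counts disagree")

    def flatten(self):
        """All releases as ``(times, xy)``: release timestamps (datetime64)
        and an ``(n, 2)`` position array, in schedule order."""
        times = np.repeat(self.dates.values, self.counts)
        xy = (np.concatenate([p for p in self.positions if len(p)])
              if self.total else np.empty((0, 2)))
        return times.astype("datetime64[s]"), xy


def seasonal_weights(production_curve, year: int = 2017) -> pd.Series:
    """Normalised per-day release weights for one calendar year.

    Each day of the year carries its month's relative production value;
    the result sums to 1.
    """
    curve = np.asarray(production_curve, dtype=float)
    if curve.shape != (12,) or np.any(curve < 0) or curve.sum() == 0:
        raise ValueError("production curve must be 12 non-negative values, not all zero")
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    w = curve[days.month - 1]
    return pd.Series(w / w.sum(), index=days, name="weight")


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` among ``weights`` (summing to 1) so counts sum
    exactly to the budget; remainders break ties toward earlier entries."""
    ideal = total * weights
    base = np.floor(ideal).astype(int)
    short = total - int(base.sum())
    if short:
        remainder = ideal - base
        # stable sort => ties go to the earliest date
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
    return base


def sample_positions(probability_raster: np.ndarray, bathymetry: BathymetryGrid,
                     n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` release points, cells ~ kelp probability (with
    replacement), position uniform within the cell around the node."""
    p = np.asarray(probability_raster, dtype=float).ravel()
    if p.sum() <= 0:
        raise ValueError("probability raster has no positive mass")
    if n == 0:
        return np.empty((0, 2))
    cells = rng.choice(p.size, size=n, p=p / p.sum())
    iy, ix = np.unravel_index(cells, probability_raster.shape)
    dx = np.diff(bathymetry.x).mean()
    dy = np.diff(bathymetry.y).mean()
    x = bathymetry.x[ix] + rng.uniform(-0.5, 0.5, n) * dx
    y = bathymetry.y[iy] + rng.uniform(-0.5, 0.5, n) * dy
    x = np.clip(x, bathymetry.x[0], bathymetry.x[-1])
    y = np.clip(y, bathymetry.y[0], bathymetry.y[-1])
    return np.column_stack([x, y])


def save_schedule(schedule: ReleaseSchedule, counts_path, positions_path) -> None:
    """Serialise as two CSVs: daily counts and flat release positions."""
    pd.DataFrame({"date": schedule.dates, "count": schedule.counts}) \
        .to_csv(counts_path, index=False)
    times, xy = schedule.flatten()
    pd.DataFrame({"date": times, "x": xy[:, 0], "y": xy[:, 1]}) \
        .to_csv(positions_path, index=False)


def load_schedule(counts_path, positions_path, seed: int = 0) -> ReleaseSchedule:
    counts = pd.read_csv(counts_path, parse_dates=["date"])
    pos = pd.read_csv(positions_path, parse_dates=["date"])
    dates = pd.DatetimeIndex(counts["date"])
    grouped = {d: g[["x", "y"]].to_numpy() for d, g in pos.groupby("date")}
    positions = [grouped.get(d, np.empty((0, 2))) for d in dates]
    return ReleaseSchedule(dates=dates, counts=counts["count"].to_numpy(),
                           positions=positions,
                           total=int(counts["count"].sum()), seed=seed)


def build_schedule(probability_raster: np.ndarray, bathymetry: BathymetryGrid,
                   production_curve=DEFAULT_PRODUCTION_CURVE,
                   total: int = 10_000, seed: int = 0,
                   year: int = 2017) -> ReleaseSchedule:
    """Full release schedule: largest-remainder daily counts times the
    seasonal weights, positions drawn per day from the kelp raster."""
    if total <= 0:
        raise ValueError("total particle budget must be positive")
    weights = seasonal_weights(production_curve, year=year)
    counts = _largest_remainder(total, weights.to_numpy())
    rng = np.random.default_rng(seed)
    positions = [sample_positions(probability_raster, bathymetry, int(c), rng)
                 for c in counts]
    return ReleaseSchedule(dates=weights.index, counts=counts,
                           positions=positions, total=total, seed=seed)
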