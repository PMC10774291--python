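"""Suitability of environmental conditions for dense shelf water transport.

Dense shelf water transport (DSWT) is a gravitational circulation: when
water along the coast becomes denser than water offshore (here through
winter cooling), the dense coastal water slides offshore along the seabed.
Conditions are classified as suitable for DSWT when three requirements hold
simultaneously:

1. a negative cross-shore bottom density gradient, d(rho)/dx < 0 with x
   increasing offshore (denser water at the coast);
2. a stratified water column, measured by the potential energy anomaly

       phi = (1/h) * integral_{-h}^{0} (rho_mean - rho) g z dz   [J/m^3],

   the energy per unit volume needed to fully mix the column (0 when fully
   mixed); averaged over the analysis region, phi must exceed a threshold
   (default 5 J/m^3);
3. the stratifying tendency of the gravitational circulation must exceed
   the destratifying tendency of wind mixing,

       (1/320) g^2 h^4 / (rho K_mz) (d rho/dx)^2  >  delta kappa_s rho_a W^3 / h,

   with kappa_s = 0.03 (0.63 + 0.066 W^{1/3}) / 1000 the surface wind-stress
   drag coefficient — except when the wind blows onshore (direction-from
   within a configured sector, default 225-315 deg), which enhances rather
   than disrupts the circulation and overrides the wind-mixing veto.

Tidal mixing is not modelled (the target setting is microtidal) and density
gradients are taken as thermally driven; salinity plays no separate role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BathymetryGrid, FieldSeries

__all__ = [
    "DSWTConstants",
    "DSWTState",
    "StratificationProfile",
    "potential_energy_anomaly",
    "horizontal_density_gradient",
    "drag_coefficient",
    "mixing_criterion",
    "is_onshore_wind",
    "classify",
    "states_to_frame",
    "monthly_suitability",
]


@dataclass(frozen=True)
class DSWTConstants:
    """Physical constants and thresholds of the three-condition test."""

    g: float = 9.81                  # gravitational acceleration, m/s^2
    K_mz: float = 1e-2               # vertical eddy diffusivity, m^2/s
    delta: float = 3e-3              # wind mixing efficiency
    rho_air: float = 1.2             # air density, kg/m^3
    phi_threshold: float = 5.0       # region-mean stratification cut, J/m^3
    onshore_sector: tuple[float, float] = (225.0, 315.0)  # deg, inclusive


@dataclass(frozen=True)
class StratificationProfile:
    """Vertical density profile of one water column.

    ``z`` ascends from the bed (-h) to the surface (0), in meters;
    ``rho`` is the density (kg/m^3) at each ``z``.
    """

    z: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))
        if self.z.ndim != 1 or self.z.shape != self.rho.shape:
            raise ValueError("z and rho must be matching 1-D arrays")
        if np.any(np.diff(self.z) < 0):
            raise ValueError("z must be non-decreasing (bed to surface)")
        if self.h <= 0:
            raise ValueError("water depth must be positive")
        if np.any(self.rho <= 0):
            raise ValueError("densities must be positive")

    @property
    def h(self) -> float:
        return float(-self.z[0])


@dataclass(frozen=True)
class DSWTState:
    """Per-timestep condition values, flags and the combined verdict."""

    timestamp: pd.Timestamp
    gradient: float          # regional d(rho)/dx, kg/m^4
    phi: float               # region-mean potential energy anomaly, J/m^3
    grav_term: float         # gravitational stratifying term, J/m^3/s
    wind_term: float         # wind-mixing destratifying term, J/m^3/s
    onshore: bool
    gradient_ok: bool
    stratified_ok: bool
    mixing_ok: bool
    suitable: bool

    @staticmethod
    def combine(gradient_ok: bool, stratified_ok: bool,
                mixing_ok: bool, onshore: bool) -> bool:
        """The boolean structure of the three-condition test."""
        return bool(gradient_ok and stratified_ok and (mixing_ok or onshore))


def potential_energy_anomaly(profile: StratificationProfile,
                             g: float = 9.81) -> float:
    """Potential energy anomaly phi (J/m^3) of one water column.

    The profile is treated as piecewise linear between its samples, which
    makes the integrand ``(rho_mean - rho) g z`` piecewise quadratic;
    per-interval Simpson quadrature therefore integrates it exactly, so the
    two-layer (g drho h / 8) and linear-profile (g drho h / 12) closed
    forms are reproduced to rounding at any layer count.  phi is positive
    for a stably stratified column (lighter water on top), zero for a
    uniform one, and invariant to adding a constant to the profile.
    """
    z, rho = profile.z, profile.rho
    h = profile.h
    rho_mean = np.trapezoid(rho, z) / h  # exact for piecewise-linear rho
    q = (rho_mean - rho) * g * z
    q_mid = (rho_mean - 0.5 * (rho[:-1] + rho[1:])) * g * 0.5 * (z[:-1] + z[1:])
    dz = np.diff(z)
    return float((dz / 6.0 * (q[:-1] + 4.0 * q_mid + q[1:])).sum() / h)


def horizontal_density_gradient(distances, densities) -> float:
    """OLS slope (kg/m^4) of bottom density against offshore distance.

    With x increasing offshore, denser water at the coast gives a negative
    slope.  Requires at least two samples.
    """
    x = np.asarray(distances, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if x.size < 2 or x.size != rho.size:
        raise ValueError("need >= 2 matched (distance, density) samples")
    xc = x - x.mean()
    return float((xc * (rho - rho.mean())).sum() / (xc * xc).sum())


def drag_coefficient(wind_speed: float) -> float:
    """Surface wind-stress drag coefficient kappa_s (dimensionless).

    kappa_s = 0.03 (0.63 + 0.066 W^{1/3}) / 1000 for wind speed W >= 0.
    """
    W = np.asarray(wind_speed, dtype=float)
    if np.any(W < 0):
        raise ValueError("wind speed must be >= 0")
    out = 0.03 * (0.63 + 0.066 * np.cbrt(W)) / 1000.0
    return float(out) if np.isscalar(wind_speed) else out


def mixing_criterion(h: float, rho: float, drho_dx: float, wind_speed: float,
                     constants: DSWTConstants = DSWTConstants()):
    """Gravitational vs wind-mixing competition.

    Returns ``(gravitational_term, wind_term, flag)`` in J/m^3/s, the flag
    true when the gravitational stratifying term exceeds the wind-mixing
    term.
    """
    h = np.asarray(h, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(h <= 0) or np.any(rho <= 0):
        raise ValueError("h and rho must be positive")
    g = constants.g
    grav = (g * g * h ** 4) / (320.0 * rho * constants.K_mz) \
        * np.asarray(drho_dx, dtype=float) ** 2
    kappa_s = 0.03 * (0.63 + 0.066 * np.cbrt(np.asarray(wind_speed, dtype=float))) / 1000.0
    wind = constants.delta * kappa_s * constants.rho_air \
        * np.asarray(wind_speed, dtype=float) ** 3 / h
    return grav, wind, grav > wind


def is_onshore_wind(direction_from, sector: tuple[float, float] = (225.0, 315.0)):
    """Whether a direction-from (deg CW from north) lies in the onshore
    sector, bounds inclusive.  Sectors wrapping through north are allowed
    (lo > hi)."""
    d = np.mod(np.asarray(direction_from, dtype=float), 360.0)
    lo, hi = sector
    if lo <= hi:
        out = (d >= lo) & (d <= hi)
    else:
        out = (d >= lo) | (d <= hi)
    return bool(out) if np.isscalar(direction_from) else out


# -- regional classification ---------------------------------------------


def _pea_raster(fields: FieldSeries, chunk: int = 256) -> np.ndarray:
    """Per-cell potential energy anomaly (nt, ny, nx) from the stored
    vertical density profiles.

    Same per-interval Simpson quadrature as
    :func:`potential_energy_anomaly`, vectorised over the level axis in
    the fractional coordinate l (z = -h (1 - l), so the 1/h prefactor and
    the dz = h dl substitution cancel).  Land columns (h = 0) come out NaN.
    """
    if fields.rho_profile is None:
        raise ValueError("fields carry no vertical density profiles")
    levels = fields.profile_levels  # 0=bed .. 1=surface
    h = fields.grid.depth  # (ny, nx)
    nt = fields.time.size
    out = np.empty((nt,) + fields.grid.shape)
    g = 9.81
    zl = -(1.0 - levels)[:, None, None] * h[None]  # (nz, ny, nx)
    zl_mid = 0.5 * (zl[:-1] + zl[1:])
    dl = np.diff(levels)[:, None, None]
    for i0 in range(0, nt, chunk):
        sl = slice(i0, min(i0 + chunk, nt))
        rho = fields.rho_profile[sl].astype(np.float64)  # (tc, nz, ny, nx)
        rho_mean = np.trapezoid(rho, levels, axis=1)[:, None]  # (tc, 1, ny, nx)
        q = (rho_mean - rho) * g * zl[None]
        rho_mid = 0.5 * (rho[:, :-1] + rho[:, 1:])
        q_mid = (rho_mean - rho_mid) * g * zl_mid[None]
        phi = (dl[None] / 6.0 * (q[:, :-1] + 4.0 * q_mid + q[:, 1:])).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[sl] = phi * h[None] / h[None]
    return out


def _circular_mean_direction(direction_deg: np.ndarray, axis=None) -> np.ndarray:
    rad = np.radians(direction_deg)
    s = np.nanmean(np.sin(rad), axis=axis)
    c = np.nanmean(np.cos(rad), axis=axis)
    return np.mod(np.degrees(np.arctan2(s, c)), 360.0)


def classify(fields: FieldSeries, bathymetry: BathymetryGrid,
             region: np.ndarray | None = None,
             constants: DSWTConstants = DSWTConstants(),
             shelf_edge_depth: float = 200.0) -> list[DSWTState]:
    """Classify every timestep of a forcing series.

    ``region`` is a boolean cell mask; by default the wet shelf (depth <=
    ``shelf_edge_depth``).  Per timestep: the density gradient is the mean
    of per-alongshore-row OLS slopes of bottom density over the region's
    shelf transects; phi is averaged over the region; the mixing criterion
    uses region means of depth, bottom density and wind.
    """
    wet_shelf = bathymetry.wet & (bathymetry.depth <= shelf_edge_depth)
    region = wet_shelf if region is None else (np.asarray(region, bool) & wet_shelf)
    if not region.any():
        raise ValueError("region contains no wet shelf cells")

    nt = fields.time.size
    # per-row OLS slopes, averaged over rows with >= 2 region cells
    slopes = []
    for j in range(bathymetry.y.size):
        sel = region[j]
        if sel.sum() < 2:
            continue
        x = bathymetry.x[sel]
        mx, _ = bathymetry.metric_factors(bathymetry.y[j])
        xc = (x - x.mean()) * float(mx)
        rho_rows = fields.rho_bottom[:, j, sel].astype(np.float64)  # (nt, k)
        slopes.append((xc * (rho_rows - rho_rows.mean(axis=1, keepdims=True))).sum(axis=1)
                      / (xc * xc).sum())
    if not slopes:
        raise ValueError("no region row has >= 2 cells for a transect")
    gradient = np.mean(slopes, axis=0)  # (nt,)

    pea = _pea_raster(fields)
    phi = np.nanmean(np.where(region[None], pea, np.nan), axis=(1, 2))

    h_mean = float(bathymetry.depth[region].mean())
    rho_mean = fields.rho_bottom[:, region].astype(np.float64).mean(axis=1)
    w_mean = fields.wind_speed[:, region].astype(np.float64).mean(axis=1)
    dir_mean = _circular_mean_direction(
        fields.wind_dir[:, region].astype(np.float64), axis=1)

    grav, wind, mixing_ok = mixing_criterion(h_mean, rho_mean, gradient,
                                             w_mean, constants)
    onshore = is_onshore_wind(dir_mean, constants.onshore_sector)
    gradient_ok = gradient < 0.0
    stratified_ok = phi > constants.phi_threshold

    idx = pd.DatetimeIndex(fields.time)
    return [
        DSWTState(
            timestamp=idx[i],
            gradient=float(gradient[i]),
            phi=float(phi[i]),
            grav_term=float(grav[i]),
            wind_term=float(wind[i]),
            onshore=bool(onshore[i]),
            gradient_ok=bool(gradient_ok[i]),
            stratified_ok=bool(stratified_ok[i]),
            mixing_ok=bool(mixing_ok[i]),
            suitable=DSWTState.combine(gradient_ok[i], stratified_ok[i],
                                       mixing_ok[i], onshore[i]),
        )
        for i in range(nt)
    ]


def states_to_frame(states: list[DSWTState]) -> pd.DataFrame:
    """Tabulate classified states (timestamp index)."""
    return pd.DataFrame(
        {
            "gradient": [s.gradient for s in states],
            "phi": [s.phi for s in states],
            "grav_term": [s.grav_term for s in states],
            "wind_term": [s.wind_term for s in states],
            "onshore": [s.onshore for s in states],
            "suitable": [s.suitable for s in states],
        },
        index=pd.DatetimeIndex([s.timestamp for s in states], name="timestamp"),
    )


def monthly_suitability(states: list[DSWTState],
                        year: int | None = None) -> pd.Series:
    """Percent of timesteps per calendar month with suitable conditions.

    ``year`` restricts the tally to one calendar year (recommended when the
    series runs past new year so each month is counted once).
    """
    if not states:
        raise ValueError("no states to summarise")
    df = states_to_frame(states)
    if year is not None:
        df = df[df.index.year == year]
    out = df["suitable"].groupby(df.index.month).mean() * 100.0
    out = out.reindex(range(1, 13), fill_value=0.0)
    out.index.name = "month"
    out.name = "suitable_percent"
    return out
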