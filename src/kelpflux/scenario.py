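"""Idealised shelf scenario generator with known ground truth.

The generator emulates the forcing structure that drives cross-shelf export
of sinking kelp detritus on a mid-latitude shelf, without attempting any
hydrodynamic realism beyond what the downstream analysis consumes:

* a shelf profile that slopes gently to ~50 m, steepens to the 200 m shelf
  edge, and continues into deep water (>= 1000 m at the offshore boundary);
* a cross-shore bottom density gradient that is negative (denser at the
  coast) through the cold season and positive in the warm season;
* episodic dense-shelf-water pulses — square-wave events of offshore bottom
  flow (~0.15 m/s) during which the water column is stratified — whose
  monthly duty cycle ramps up through autumn, peaks in early winter and
  decays in spring;
* an alongshore background current present year-round, onshore bottom flow
  in the warm season, winds with warm-season seabreezes and cold-season
  onshore storms, and a kelp-occurrence probability declining with depth
  and vanishing beyond ~50 m.

Everything is a closed-form function of the configuration, so tests can
verify fields against independently evaluated formulas, and the scheduled
pulse windows provide exact ground truth for export accounting.

Southern-hemisphere seasons are the default: the cold season spans the
middle of the calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import BathymetryGrid, FieldSeries, Scenario

__all__ = [
    "ShelfScenarioConfig",
    "make_bathymetry",
    "make_forcing",
    "make_kelp_probability",
    "make_scenario",
    "depth_profile",
    "pulse_indicator",
]

#: default monthly fraction of time with dense-shelf-water pulses
#: (Jan..Dec, southern hemisphere): none through the warm season, ~20% in
#: April, peaking above 60% in June, decaying through spring.
DEFAULT_PULSE_DUTY = (0.0, 0.0, 0.0, 0.20, 0.60, 0.65, 0.50, 0.35, 0.10,
                      0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ShelfScenarioConfig:
    """Parameters of the idealised shelf scenario (lengths m, speeds m/s)."""

    # domain and grid
    cross_shore_length: float = 100_000.0
    alongshore_length: float = 40_000.0
    grid_spacing: float = 2_000.0
    # depth profile: gentle slope to the inner shelf, steeper to the edge,
    # steepest down the slope to the offshore boundary
    inner_shelf_depth: float = 50.0
    inner_shelf_distance: float = 40_000.0
    shelf_edge_depth: float = 200.0
    shelf_edge_distance: float = 60_000.0
    offshore_depth: float = 1_200.0
    # time axis
    start_date: str = "2017-01-01"
    n_days: int = 396
    snapshot_hours: float = 3.0
    # season schedule (calendar months); remaining months are transitional
    warm_months: tuple[int, ...] = (11, 12, 1, 2, 3)
    cold_months: tuple[int, ...] = (5, 6, 7, 8, 9)
    # density structure
    rho0: float = 1025.0
    cross_shore_gradient: float = 3e-6  # kg/m^4 magnitude of d(rho)/dx
    strat_delta: float = 0.5            # surface-to-bed drop during pulses, kg/m^3
    mixed_delta: float = 0.02           # residual stratification otherwise
    n_profile_levels: int = 10
    # dense-shelf-water pulses
    pulse_speed: float = 0.15
    pulse_duration_days: float = 2.0
    pulse_gap_days: float | None = None          # constant duty override
    pulse_duty_by_month: tuple[float, ...] = DEFAULT_PULSE_DUTY
    pulse_ramp_hours: float = 0.0
    pulse_offshore_efold: float = 20_000.0  # decay scale past the shelf edge
    # background circulation
    alongshore_speed: float = 0.05
    onshore_speed: float = 0.02
    coastal_taper_depth: float = 10.0  # cross-shore flow tapers to 0 at the coast
    # wind regimes (direction = where the wind comes from, deg CW from N)
    seabreeze_base: float = 3.0
    seabreeze_amp: float = 9.0
    seabreeze_dir: float = 180.0
    storm_speed: float = 15.0
    storm_dir: float = 270.0
    storm_period_days: float = 7.0
    storm_duration_days: float = 1.0
    calm_wind_speed: float = 5.0
    calm_wind_dir: float = 90.0
    # kelp
    kelp_depth_limit: float = 50.0
    # reproducibility
    seed: int = 0
    velocity_noise: float = 0.0  # optional Gaussian jitter on bottom currents

    def __post_init__(self) -> None:
        for name in ("cross_shore_length", "alongshore_length", "grid_spacing",
                     "inner_shelf_depth", "shelf_edge_depth", "offshore_depth",
                     "inner_shelf_distance", "shelf_edge_distance",
                     "pulse_speed", "pulse_duration_days", "kelp_depth_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.inner_shelf_distance < self.shelf_edge_distance
                <= self.cross_shore_length):
            raise ValueError("require inner_shelf_distance < shelf_edge_distance "
                             "<= cross_shore_length")
        if not (self.inner_shelf_depth < self.shelf_edge_depth
                < self.offshore_depth):
            raise ValueError("depth profile parameters must increase offshore")
        if self.offshore_depth < 1000.0:
            raise ValueError("offshore boundary must reach at least 1000 m")
        if len(self.pulse_duty_by_month) != 12:
            raise ValueError("pulse_duty_by_month needs 12 entries")
        if self.velocity_noise < 0:
            raise ValueError("velocity_noise must be >= 0")

    def season_of(self, month: int) -> str:
        if month in self.warm_months:
            return "warm"
        if month in self.cold_months:
            return "cold"
        return "transition"

    def replace(self, **kw) -> "ShelfScenarioConfig":
        return replace(self, **kw)


# -- bathymetry -----------------------------------------------------------


def depth_profile(config: ShelfScenarioConfig, x) -> np.ndarray:
    """Closed-form cross-shore depth profile (m) at offshore distance x.

    Piecewise linear through (0, 0), (inner_shelf_distance,
    inner_shelf_depth), (shelf_edge_distance, shelf_edge_depth) and
    (cross_shore_length, offshore_depth); monotone by construction.
    """
    xp = [0.0, config.inner_shelf_distance, config.shelf_edge_distance,
          config.cross_shore_length]
    fp = [0.0, config.inner_shelf_depth, config.shelf_edge_depth,
          config.offshore_depth]
    return np.interp(np.asarray(x, dtype=float), xp, fp)


def make_bathymetry(config: ShelfScenarioConfig) -> BathymetryGrid:
    """Rectilinear node grid with the configured shelf profile.

    The coast is the x = 0 column, which is the only land; depth is
    uniform alongshore and monotone non-decreasing offshore, reaching the
    shelf-edge depth exactly at the configured shelf-edge distance.
    """
    dx = config.grid_spacing
    x = np.arange(0.0, config.cross_shore_length + dx / 2, dx)
    y = np.arange(0.0, config.alongshore_length + dx / 2, dx)
    depth_row = depth_profile(config, x)
    depth = np.tile(depth_row, (y.size, 1))
    land = depth <= 0.0
    return BathymetryGrid(x=x, y=y, depth=depth, land=land)


# -- pulse schedule -------------------------------------------------------


def _month_duty(config: ShelfScenarioConfig, month: int) -> float:
    if config.season_of(month) == "warm":
        return 0.0
    if config.pulse_gap_days is not None:
        cycle = config.pulse_duration_days + config.pulse_gap_days
        return config.pulse_duration_days / cycle
    return float(config.pulse_duty_by_month[month - 1])


def pulse_indicator(config: ShelfScenarioConfig, times) -> np.ndarray:
    """Fraction in [0, 1] of full pulse strength at each timestamp.

    Pulses are square waves of ``pulse_duration_days`` placed periodically
    within each calendar month so that the month's on-fraction equals its
    configured duty cycle, with an optional linear ramp at the edges.  This
    is the generator's ground truth for when dense-shelf-water flow is on.
    """
    idx = pd.DatetimeIndex(np.asarray(times))
    day_of_month = (idx.day - 1) + idx.hour / 24.0 + idx.minute / 1440.0
    out = np.zeros(idx.size)
    ramp_d = config.pulse_ramp_hours / 24.0
    for m in range(1, 13):
        sel = idx.month == m
        if not sel.any():
            continue
        duty = _month_duty(config, m)
        if duty <= 0.0:
            continue
        duty = min(duty, 1.0)
        cycle = config.pulse_duration_days / duty
        phase = np.mod(day_of_month[sel], cycle)
        on = np.clip(
            np.minimum(phase, config.pulse_duration_days - phase) / ramp_d
            if ramp_d > 0 else (phase < config.pulse_duration_days).astype(float),
            0.0, 1.0,
        )
        if ramp_d > 0:
            on = np.where(phase < config.pulse_duration_days, on, 0.0)
        out[np.asarray(sel)] = on
    return out


# -- forcing --------------------------------------------------------------


def _wind_series(config: ShelfScenarioConfig, idx: pd.DatetimeIndex):
    """Uniform wind speed/direction time series per the configured regimes."""
    month = idx.month.to_numpy()
    season = np.array([config.season_of(m) for m in month])
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    speed = np.full(idx.size, config.calm_wind_speed)
    direction = np.full(idx.size, config.calm_wind_dir)
    # warm season: diurnal seabreeze peaking in the afternoon
    warm = season == "warm"
    diurnal = np.maximum(0.0, np.sin(2 * np.pi * (hour - 6.0) / 24.0))
    speed[warm] = config.seabreeze_base + config.seabreeze_amp * diurnal[warm]
    direction[warm] = config.seabreeze_dir
    # cold season: periodic onshore storms over the calm background
    cold = season == "cold"
    day_of_year = (idx.dayofyear - 1) + hour / 24.0
    storm_phase = np.mod(day_of_year, config.storm_period_days)
    in_storm = cold & (storm_phase < config.storm_duration_days)
    speed[in_storm] = config.storm_speed
    direction[in_storm] = config.storm_dir
    return speed, direction


def make_forcing(config: ShelfScenarioConfig,
                 bathymetry: BathymetryGrid) -> FieldSeries:
    """Generate the full forcing series on the scenario grid.

    Cross-shore bottom velocity is the sum of the pulse term (offshore at
    ``pulse_speed`` on the shelf during scheduled pulses, decaying
    exponentially past the shelf edge) and warm-season onshore flow; both
    taper linearly to zero where depth < ``coastal_taper_depth`` so there is
    no flow through the coastline.  Bottom density carries the seasonal
    cross-shore gradient; the vertical profile is linear in height with a
    surface-to-bed drop of ``strat_delta`` during pulses and
    ``mixed_delta`` otherwise.
    """
    step = np.timedelta64(int(round(config.snapshot_hours * 3600)), "s")
    n_steps = int(round(config.n_days * 24 / config.snapshot_hours)) + 1
    t0 = np.datetime64(config.start_date, "s")
    times = t0 + step * np.arange(n_steps)
    idx = pd.DatetimeIndex(times)
    month = idx.month.to_numpy()
    season = np.array([config.season_of(m) for m in month])

    depth = bathymetry.depth
    wet = bathymetry.wet
    taper = np.clip(depth / config.coastal_taper_depth, 0.0, 1.0) * wet
    x2d = np.broadcast_to(bathymetry.x, depth.shape)
    # spatial shape of the pulse: full speed on the shelf, exponential
    # decay continuing down the slope past the edge
    past_edge = np.maximum(0.0, x2d - config.shelf_edge_distance)
    pulse_shape = taper * np.exp(-past_edge / config.pulse_offshore_efold)

    pulse = pulse_indicator(config, times)  # (nt,)
    onshore = (season == "warm").astype(float)
    grad_sign = np.where(season == "warm", 1.0, -1.0)

    u = (pulse[:, None, None] * config.pulse_speed * pulse_shape[None]
         - onshore[:, None, None] * config.onshore_speed * taper[None])
    v = np.where(wet[None], config.alongshore_speed, 0.0) * np.ones((n_steps, 1, 1))
    if config.velocity_noise > 0:
        rng = np.random.default_rng(config.seed)
        u = u + rng.normal(0.0, config.velocity_noise, u.shape) * wet[None]
        v = v + rng.normal(0.0, config.velocity_noise, v.shape) * wet[None]

    g = config.cross_shore_gradient
    rho_bottom = (config.rho0
                  + grad_sign[:, None, None] * g * x2d[None]).astype(np.float64)

    delta = np.where(pulse > 0, config.mixed_delta
                     + pulse * (config.strat_delta - config.mixed_delta),
                     config.mixed_delta)
    levels = np.linspace(0.0, 1.0, config.n_profile_levels)
    rho_profile = (rho_bottom[:, None]
                   - delta[:, None, None, None] * levels[None, :, None, None])

    wind_speed_1d, wind_dir_1d = _wind_series(config, idx)
    ones = np.ones((1,) + depth.shape)
    return FieldSeries(
        grid=bathymetry,
        time=times,
        u=u.astype(np.float32),
        v=v.astype(np.float32),
        rho_bottom=rho_bottom.astype(np.float32),
        wind_speed=(wind_speed_1d[:, None, None] * ones).astype(np.float32),
        wind_dir=(wind_dir_1d[:, None, None] * ones).astype(np.float32),
        rho_profile=rho_profile.astype(np.float32),
        profile_levels=levels,
    )


# -- kelp probability -----------------------------------------------------


def make_kelp_probability(bathymetry: BathymetryGrid,
                          config: ShelfScenarioConfig) -> np.ndarray:
    """Kelp-occurrence probability raster declining linearly with depth.

    Probability is ``1 - depth / kelp_depth_limit`` on wet cells, clipped
    to [0, 1]; zero on land and beyond the depth limit (~50 m by default,
    the deep limit of kelp reefs on the shelf).
    """
    p = np.clip(1.0 - bathymetry.depth / config.kelp_depth_limit, 0.0, 1.0)
    p[bathymetry.land] = 0.0
    p[bathymetry.depth > config.kelp_depth_limit] = 0.0
    return p


def make_scenario(config: ShelfScenarioConfig | None = None) -> Scenario:
    """Bathymetry + forcing + kelp probability in one call."""
    config = config or ShelfScenarioConfig()
    bathy = make_bathymetry(config)
    fields = make_forcing(config, bathy)
    kelp = make_kelp_probability(bathy, config)
    return Scenario(bathymetry=bathy, fields=fields, kelp_prob=kelp)
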