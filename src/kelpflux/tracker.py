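"""Lagrangian tracking of sinking detritus with bottom-layer currents.

Particles represent negatively buoyant kelp fragments travelling with the
deepest model layer's horizontal currents.  Each timestep applies classical
4th-order Runge-Kutta advection through the (bilinear-in-space,
linear-in-time) velocity field, followed by an uncorrelated Gaussian random
walk with per-axis standard deviation sqrt(2 K_h dt) that represents
unresolved horizontal stirring (K_h = 10 m^2/s by default).

Two sensitivity switches mirror common treatments of bed-load behaviour:

* a threshold velocity v_crit — a particle holds position during any step
  whose local current speed is below the threshold (detritus at rest on
  the seabed; by default the hold suppresses the random walk too);
* a logarithmic bottom-profile correction that rescales the layer velocity
  from mid-layer height to a fixed height above the bed.

Particles that would step onto land are frozen at their last wet position
("beached"); particles leaving the open boundary are deactivated; particles
reaching the deactivation depth (default 1000 m, past the deepest export
level of interest) are deactivated as exported.  There are no vertical
dynamics: no sinking-speed model and no resuspension.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .grids import BathymetryGrid, FieldSeries
from .releases import ReleaseSchedule

__all__ = [
    "ParticleState",
    "TrackerOptions",
    "TrajectorySet",
    "rk4_step",
    "brownian_step",
    "log_profile_correction",
    "advect",
]


class ParticleState(IntEnum):
    ACTIVE = 0
    BEACHED = 1
    EXPORTED = 2        # deactivated past the deepest tracked depth
    OUT_OF_DOMAIN = 3


@dataclass(frozen=True)
class TrackerOptions:
    """Tracking parameters (SI units)."""

    dt: float = 900.0                 # advection timestep, s
    K_h: float = 10.0                 # horizontal diffusivity, m^2/s
    v_crit: float | None = None       # threshold speed, m/s (None = off)
    gate_diffusion: bool = True       # hold also suppresses the random walk
    log_profile: bool = False
    z0: float = 1e-3                  # bed roughness length, m
    target_height: float = 1.0        # height the velocity is rescaled to, m
    bottom_layer_thickness: float = 5.0
    record_hours: float = 6.0         # trajectory recording interval
    deactivate_depth: float = 1000.0
    min_depth: float = 0.5            # beaching depth, m
    periodic_y: bool = False          # treat the alongshore axis as a channel
    end_time: np.datetime64 | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.K_h < 0:
            raise ValueError("K_h must be >= 0")
        if self.v_crit is not None and self.v_crit < 0:
            raise ValueError("v_crit must be >= 0")


def rk4_step(sample, px, py, t_sec: float, dt: float, metric=None):
    """One classical RK4 step of dX/dt = V(X, t).

    ``sample(px, py, t) -> (u, v)`` returns velocity in m/s at coordinate
    positions; ``metric(py) -> (mx, my)`` gives meters per coordinate unit
    (identity when omitted, i.e. a Cartesian frame in meters).  NaN
    velocities (out-of-water points) are treated as zero at stage
    evaluations.  Returns the new ``(px, py)``.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)

    def f(qx, qy, t):
        u, v = sample(qx, qy, t)
        u = np.nan_to_num(np.asarray(u, dtype=float))
        v = np.nan_to_num(np.asarray(v, dtype=float))
        if metric is None:
            return u, v
        mx, my = metric(qy)
        return u / mx, v / my

    k1x, k1y = f(px, py, t_sec)
    k2x, k2y = f(px + 0.5 * dt * k1x, py + 0.5 * dt * k1y, t_sec + 0.5 * dt)
    k3x, k3y = f(px + 0.5 * dt * k2x, py + 0.5 * dt * k2y, t_sec + 0.5 * dt)
    k4x, k4y = f(px + dt * k3x, py + dt * k3y, t_sec + dt)
    return (px + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x),
            py + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y))


def brownian_step(rng: np.random.Generator, K_h: float, dt: float,
                  n: int = 1) -> np.ndarray:
    """Random-walk displacements, shape (n, 2), in meters.

    Independent Gaussian components with standard deviation
    sqrt(2 K_h dt) per axis, the discrete walk whose ensemble mean-square
    displacement grows as 4 K_h t in two dimensions.
    """
    if K_h < 0:
        raise ValueError("K_h must be >= 0")
    if K_h == 0:
        return np.zeros((n, 2))
    return rng.normal(0.0, np.sqrt(2.0 * K_h * dt), size=(n, 2))


def log_profile_correction(velocity, layer_thickness: float,
                           target_height: float, z0: float):
    """Rescale a bottom-layer velocity to a target height above the bed.

    Assumes a logarithmic profile u(z) ~ ln(z / z0): the layer velocity is
    taken to represent mid-layer height and scaled by
    ``ln(target/z0) / ln(mid/z0)``, preserving direction.  Identity when
    the target equals mid-layer height.
    """
    mid = layer_thickness / 2.0
    if z0 <= 0 or target_height <= z0 or mid <= z0:
        raise ValueError("require heights > z0 > 0")
    factor = np.log(target_height / z0) / np.log(mid / z0)
    return np.asarray(velocity, dtype=float) * factor


@dataclass
class TrajectorySet:
    """Recorded particle trajectories on a shared record-time axis.

    ``xy`` has shape (n, nrec, 2) and ``depth`` (n, nrec), NaN before a
    particle's release and after its deactivation; the record right after
    a deactivation-by-depth carries the deactivation position so deep
    crossings are never lost between records.
    """

    release_times: np.ndarray   # (n,) datetime64[s]
    release_xy: np.ndarray      # (n, 2)
    record_times: np.ndarray    # (nrec,) datetime64[s]
    xy: np.ndarray              # (n, nrec, 2) float32
    depth: np.ndarray           # (n, nrec) float32
    state: np.ndarray           # (n,) ParticleState codes

    @property
    def n_particles(self) -> int:
        return self.release_times.size

    def state_counts(self) -> dict[str, int]:
        return {s.name.lower(): int((self.state == s).sum()) for s in ParticleState}

    def to_dataset(self):
        import xarray as xr

        return xr.Dataset(
            {
                "x": (("particle", "record"), self.xy[:, :, 0]),
                "y": (("particle", "record"), self.xy[:, :, 1]),
                "depth": (("particle", "record"), self.depth, {"units": "m"}),
                "state": (("particle",), self.state.astype("i4")),
                "release_x": (("particle",), self.release_xy[:, 0]),
                "release_y": (("particle",), self.release_xy[:, 1]),
                "release_time": (("particle",), self.release_times),
            },
            coords={"record": ("record", self.record_times)},
        )

    @classmethod
    def from_dataset(cls, ds) -> "TrajectorySet":
        return cls(
            release_times=np.asarray(ds["release_time"]).astype("datetime64[s]"),
            release_xy=np.column_stack([np.asarray(ds["release_x"]),
                                        np.asarray(ds["release_y"])]),
            record_times=np.asarray(ds["record"]).astype("datetime64[s]"),
            xy=np.stack([np.asarray(ds["x"]), np.asarray(ds["y"])], axis=-1),
            depth=np.asarray(ds["depth"]),
            state=np.asarray(ds["state"]).astype(np.int8),
        )

    def save(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path) -> "TrajectorySet":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def advect(schedule: ReleaseSchedule, fields: FieldSeries,
           bathymetry: BathymetryGrid,
           options: TrackerOptions = TrackerOptions()) -> TrajectorySet:
    """Track every scheduled particle through the forcing series.

    Deterministic given ``options.seed``.  Raises if the schedule starts
    before the forcing series or runs past its end.
    """
    release_times, release_xy = schedule.flatten()
    n = release_times.size
    t_field0, t_field1 = fields.t_seconds[0], fields.t_seconds[-1]
    rel_sec = release_times.astype("int64").astype(float)
    t_end = (float(np.datetime64(options.end_time, "s").astype("int64"))
             if options.end_time is not None else t_field1)
    if n and (rel_sec.min() < t_field0 or rel_sec.max() > t_end or t_end > t_field1):
        raise ValueError("release schedule is outside the forcing series span")

    dt = options.dt
    rec_every = max(1, int(round(options.record_hours * 3600.0 / dt)))
    t_start = rel_sec.min() if n else t_field0
    n_steps = int(np.ceil((t_end - t_start) / dt))
    rec_steps = np.arange(0, n_steps + 1, rec_every)
    record_sec = t_start + rec_steps * dt
    nrec = rec_steps.size

    xy = np.full((n, nrec, 2), np.nan, dtype=np.float32)
    dep = np.full((n, nrec), np.nan, dtype=np.float32)
    state = np.full(n, int(ParticleState.ACTIVE), dtype=np.int8)
    started = np.zeros(n, dtype=bool)
    pos = np.full((n, 2), np.nan)
    pending_snapshot = np.zeros(n, dtype=bool)  # exported, not yet recorded

    rng = np.random.default_rng(options.seed)
    x0, x1 = bathymetry.x[0], bathymetry.x[-1]
    y0, y1 = bathymetry.y[0], bathymetry.y[-1]
    geographic = bathymetry.geographic

    log_factor = 1.0
    if options.log_profile:
        log_factor = float(log_profile_correction(
            1.0, options.bottom_layer_thickness, options.target_height,
            options.z0))

    def sample(qx, qy, t):
        qx = np.clip(qx, x0, x1)
        if options.periodic_y:
            qy = y0 + np.mod(qy - y0, y1 - y0)
        else:
            qy = np.clip(qy, y0, y1)
        u, v = fields.velocity_at(qx, qy, min(t, t_field1))
        return u * log_factor, v * log_factor

    metric = None
    if geographic:
        metric = bathymetry.metric_factors

    rec_ptr = 0

    def record(step_idx: int) -> None:
        nonlocal rec_ptr
        if rec_ptr < nrec and rec_steps[rec_ptr] == step_idx:
            live = started & (state == ParticleState.ACTIVE)
            snap = live | (pending_snapshot & started)
            if snap.any():
                xy[snap, rec_ptr] = pos[snap]
                dep[snap, rec_ptr] = bathymetry.depth_at(pos[snap, 0], pos[snap, 1])
            pending_snapshot[:] = False
            rec_ptr += 1

    for step in range(n_steps + 1):
        t = t_start + step * dt
        newly = (~started) & (rel_sec <= t) & (state == ParticleState.ACTIVE)
        if newly.any():
            pos[newly] = release_xy[newly]
            started[newly] = True
            # releases on land (kelp cells are wet, but positions are
            # jittered within the cell) beach immediately
            d = bathymetry.depth_at(pos[newly, 0], pos[newly, 1])
            bad = d < options.min_depth
            if bad.any():
                idx = np.nonzero(newly)[0][bad]
                state[idx] = ParticleState.BEACHED
        record(step)
        if step == n_steps:
            break

        live = started & (state == ParticleState.ACTIVE)
        if not live.any():
            continue
        px, py = pos[live, 0], pos[live, 1]

        u0, v0 = sample(px, py, t)
        moving = np.ones(px.size, dtype=bool)
        if options.v_crit is not None:
            moving = np.hypot(np.nan_to_num(u0), np.nan_to_num(v0)) >= options.v_crit

        nx, ny = rk4_step(sample, px, py, t, dt, metric=metric)
        nx = np.where(moving, nx, px)
        ny = np.where(moving, ny, py)

        if options.K_h > 0:
            disp = brownian_step(rng, options.K_h, dt, n=px.size)
            if options.v_crit is not None and options.gate_diffusion:
                disp[~moving] = 0.0
            if geographic:
                mx, my = bathymetry.metric_factors(ny)
                nx = nx + disp[:, 0] / mx
                ny = ny + disp[:, 1] / my
            else:
                nx = nx + disp[:, 0]
                ny = ny + disp[:, 1]

        if options.periodic_y:
            ny = y0 + np.mod(ny - y0, y1 - y0)

        live_idx = np.nonzero(live)[0]
        out = (nx < x0) | (nx > x1) | (ny < y0) | (ny > y1)
        if out.any():
            # a rim backed by land beaches the particle; a wet open
            # boundary deactivates it
            cx = np.clip(nx[out], x0, x1)
            cy = np.clip(ny[out], y0, y1)
            d_edge = bathymetry.depth_at(cx, cy)
            u_edge, _ = fields.velocity_at(cx, cy, min(t + dt, t_field1))
            dry_edge = (d_edge < options.min_depth) | np.isnan(u_edge)
            idx_out = live_idx[out]
            state[idx_out[dry_edge]] = ParticleState.BEACHED
            gone = idx_out[~dry_edge]
            state[gone] = ParticleState.OUT_OF_DOMAIN
            pos[gone] = np.nan
        ok = ~out
        if ok.any():
            cx, cy = nx[ok], ny[ok]
            d = bathymetry.depth_at(cx, cy)
            u_chk, _ = fields.velocity_at(cx, cy, min(t + dt, t_field1))
            dry = (d < options.min_depth) | np.isnan(u_chk)
            idx_ok = live_idx[ok]
            if dry.any():
                state[idx_ok[dry]] = ParticleState.BEACHED  # frozen at last wet pos
            wetm = ~dry
            if wetm.any():
                idx_wet = idx_ok[wetm]
                pos[idx_wet, 0] = cx[wetm]
                pos[idx_wet, 1] = cy[wetm]
                deep = d[wetm] >= options.deactivate_depth
                if deep.any():
                    state[idx_wet[deep]] = ParticleState.EXPORTED
                    pending_snapshot[idx_wet[deep]] = True

    return TrajectorySet(
        release_times=release_times,
        release_xy=release_xy,
        record_times=record_sec.astype("int64").astype("datetime64[s]"),
        xy=xy,
        depth=dep,
        state=state,
    )
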