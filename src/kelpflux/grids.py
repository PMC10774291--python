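"""Gridded forcing containers, NetCDF I/O and interpolation.

The package works on a rectilinear grid with ascending coordinate axes.
Synthetic scenarios use a local Cartesian frame in meters (x = cross-shore,
positive offshore with the coast on the low-x side; y = alongshore).  Real
data may instead carry lon/lat degrees, in which case metric displacements
are converted with a local equirectangular scaling (1 deg latitude =
111,320 m, longitude scaled by cos(latitude)); at shelf scale the error of
that approximation is well below a permille.

Velocity interpolation is bilinear in space and linear in time.  Next to
land, the bilinear weights of land nodes are zeroed and the remaining
weights renormalised, the standard particle-tracking treatment that keeps a
constant field exactly constant up to the waterline and never drags
particles onto land.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

__all__ = [
    "BathymetryGrid",
    "FieldSeries",
    "Scenario",
    "OutOfDomainError",
    "OutOfWaterError",
    "FieldValidationError",
    "load_fields",
    "load_scenario",
    "save_scenario",
    "cross_shore_transect",
]

#: meters per degree of latitude used for geographic grids
M_PER_DEG_LAT = 111_320.0


class OutOfDomainError(ValueError):
    """A queried position or time lies outside the gridded domain."""


class OutOfWaterError(ValueError):
    """A queried position is surrounded entirely by land nodes."""


class FieldValidationError(ValueError):
    """A forcing file is missing variables or violates layout invariants."""


def _check_axis(name: str, axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise FieldValidationError(f"axis {name!r} must be 1-D with >= 2 nodes")
    if not np.all(np.diff(axis) > 0):
        raise FieldValidationError(f"axis {name!r} must be strictly increasing")
    return axis


@dataclass
class BathymetryGrid:
    """Seabed depth raster with land mask on a rectilinear node grid.

    Parameters
    ----------
    x, y
        Node coordinates, strictly increasing.  Meters in the scenario
        frame, or degrees (lon, lat) when ``geographic`` is true.
    depth
        Water depth in meters below datum, shape ``(ny, nx)``, >= 0 on
        wet nodes.
    land
        Boolean land mask per node, same shape as ``depth``.
    geographic
        Whether coordinates are lon/lat degrees.
    """

    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    land: np.ndarray
    geographic: bool = False

    def __post_init__(self) -> None:
        self.x = _check_axis("x", self.x)
        self.y = _check_axis("y", self.y)
        self.depth = np.asarray(self.depth, dtype=float)
        self.land = np.asarray(self.land, dtype=bool)
        if self.depth.shape != (self.y.size, self.x.size):
            raise FieldValidationError(
                f"depth shape {self.depth.shape} does not match grid "
                f"({self.y.size}, {self.x.size})"
            )
        if self.land.shape != self.depth.shape:
            raise FieldValidationError("land mask and depth shapes disagree")
        if np.any(self.depth[~self.land] < 0):
            raise FieldValidationError("wet nodes must have depth >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    @property
    def wet(self) -> np.ndarray:
        return ~self.land

    def contains(self, px, py) -> np.ndarray:
        px = np.asarray(px, dtype=float)
        py = np.asarray(py, dtype=float)
        return (
            (px >= self.x[0]) & (px <= self.x[-1])
            & (py >= self.y[0]) & (py <= self.y[-1])
        )

    def metric_factors(self, py) -> tuple[np.ndarray, np.ndarray]:
        """Meters per coordinate unit (mx, my) at latitude/ordinate ``py``."""
        py = np.asarray(py, dtype=float)
        if not self.geographic:
            one = np.ones_like(py)
            return one, one
        my = np.full_like(py, M_PER_DEG_LAT)
        mx = M_PER_DEG_LAT * np.cos(np.radians(py))
        return mx, my

    # -- interpolation ----------------------------------------------------

    def _locate(self, axis: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = np.clip(np.searchsorted(axis, p, side="right") - 1, 0, axis.size - 2)
        w = (p - axis[i]) / (axis[i + 1] - axis[i])
        return i, w

    def bilinear_weights(self, px, py):
        """Cell indices and corner weights for bilinear interpolation.

        Returns ``(ix, iy, wx, wy)``; raises :class:`OutOfDomainError` when
        any point is outside the grid's bounding box.
        """
        px = np.atleast_1d(np.asarray(px, dtype=float))
        py = np.atleast_1d(np.asarray(py, dtype=float))
        inside = self.contains(px, py)
        if not np.all(inside):
            raise OutOfDomainError("position outside gridded domain")
        ix, wx = self._locate(self.x, px)
        iy, wy = self._locate(self.y, py)
        return ix, iy, wx, wy

    def depth_at(self, px, py):
        """Bilinearly interpolated water depth (m) at point(s)."""
        scalar = np.isscalar(px) and np.isscalar(py)
        ix, iy, wx, wy = self.bilinear_weights(px, py)
        d = self.depth
        val = (
            d[iy, ix] * (1 - wx) * (1 - wy)
            + d[iy, ix + 1] * wx * (1 - wy)
            + d[iy + 1, ix] * (1 - wx) * wy
            + d[iy + 1, ix + 1] * wx * wy
        )
        return float(val[0]) if scalar else val

    def wet_corner_weights(self, px, py):
        """Bilinear corner weights with land nodes zeroed, unnormalised.

        Returns ``(ix, iy, weights)`` where ``weights`` has shape
        ``(4, n)`` for corners in order (SW, SE, NW, NE), plus the weight
        sum ``denom``; ``denom == 0`` marks points with all-land corners.
        """
        ix, iy, wx, wy = self.bilinear_weights(px, py)
        wet = self.wet
        w = np.stack(
            [
                (1 - wx) * (1 - wy) * wet[iy, ix],
                wx * (1 - wy) * wet[iy, ix + 1],
                (1 - wx) * wy * wet[iy + 1, ix],
                wx * wy * wet[iy + 1, ix + 1],
            ]
        )
        return ix, iy, w, w.sum(axis=0)


def _as_seconds(time: np.ndarray) -> np.ndarray:
    t = np.asarray(time)
    if not np.issubdtype(t.dtype, np.datetime64):
        raise FieldValidationError("time axis must be datetime64")
    return t.astype("datetime64[s]").astype("int64").astype(float)


@dataclass
class FieldSeries:
    """Time series of gridded bottom-layer forcing.

    Arrays are ``(nt, ny, nx)`` on the nodes of ``grid``; the optional
    density profile is ``(nt, nz, ny, nx)`` sampled at fractional heights
    ``profile_levels`` above the bed (0 = bed, 1 = surface), i.e. at
    ``z = -h * (1 - level)`` in each water column.
    """

    grid: BathymetryGrid
    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    rho_bottom: np.ndarray
    wind_speed: np.ndarray
    wind_dir: np.ndarray
    rho_profile: np.ndarray | None = None
    profile_levels: np.ndarray | None = None
    _t_sec: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time).astype("datetime64[s]")
        self._t_sec = _as_seconds(self.time)
        if self.time.size < 2 or not np.all(np.diff(self._t_sec) > 0):
            raise FieldValidationError("time axis must be strictly increasing with >= 2 steps")
        shape = (self.time.size,) + self.grid.shape
        for name in ("u", "v", "rho_bottom", "wind_speed", "wind_dir"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise FieldValidationError(
                    f"variable {name!r} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        if self.rho_profile is not None:
            self.rho_profile = np.asarray(self.rho_profile)
            if self.profile_levels is None:
                raise FieldValidationError("rho_profile requires profile_levels")
            self.profile_levels = np.asarray(self.profile_levels, dtype=float)
            nz = self.profile_levels.size
            if self.rho_profile.shape != (self.time.size, nz) + self.grid.shape:
                raise FieldValidationError("rho_profile shape mismatch")

    @property
    def t_seconds(self) -> np.ndarray:
        """Time axis as POSIX seconds (float)."""
        return self._t_sec

    def seconds_of(self, when) -> float:
        return float(np.datetime64(when, "s").astype("int64"))

    def _bracket(self, t_sec: float) -> tuple[int, float]:
        ts = self._t_sec
        if t_sec < ts[0] or t_sec > ts[-1]:
            raise OutOfDomainError("time outside field series span")
        i = int(np.clip(np.searchsorted(ts, t_sec, side="right") - 1, 0, ts.size - 2))
        a = (t_sec - ts[i]) / (ts[i + 1] - ts[i])
        return i, a

    def _sample_snapshot(self, arr2d: np.ndarray, ix, iy, w, denom):
        num = (
            w[0] * arr2d[iy, ix]
            + w[1] * arr2d[iy, ix + 1]
            + w[2] * arr2d[iy + 1, ix]
            + w[3] * arr2d[iy + 1, ix + 1]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)

    def velocity_at(self, px, py, t_sec: float):
        """Bottom velocity ``(u, v)`` in m/s at point(s) and POSIX time.

        Wet-weight renormalised bilinear interpolation in space, linear in
        time.  NaN components mark points whose four surrounding nodes are
        all land ("out of water").
        """
        px = np.atleast_1d(np.asarray(px, dtype=float))
        py = np.atleast_1d(np.asarray(py, dtype=float))
        i, a = self._bracket(t_sec)
        ix, iy, w, denom = self.grid.wet_corner_weights(px, py)
        out_u = np.empty(px.shape)
        out_v = np.empty(px.shape)
        for arr, out in ((self.u, out_u), (self.v, out_v)):
            v0 = self._sample_snapshot(arr[i], ix, iy, w, denom)
            v1 = self._sample_snapshot(arr[i + 1], ix, iy, w, denom)
            out[:] = (1 - a) * v0 + a * v1
        return out_u, out_v

    def interp_velocity(self, position, when) -> tuple[float, float]:
        """Scalar convenience wrapper: velocity at one point and timestamp.

        Raises :class:`OutOfWaterError` if the point has no wet neighbour
        and :class:`OutOfDomainError` outside the grid or time span.
        """
        px, py = position
        u, v = self.velocity_at(px, py, self.seconds_of(when))
        if np.isnan(u[0]) or np.isnan(v[0]):
            raise OutOfWaterError("position has no wet neighbouring node")
        return float(u[0]), float(v[0])

    def scalar_field_at(self, name: str, px, py, t_sec: float):
        """Interpolate a named raster (e.g. ``rho_bottom``) like velocity."""
        arr = getattr(self, name)
        px = np.atleast_1d(np.asarray(px, dtype=float))
        py = np.atleast_1d(np.asarray(py, dtype=float))
        i, a = self._bracket(t_sec)
        ix, iy, w, denom = self.grid.wet_corner_weights(px, py)
        v0 = self._sample_snapshot(arr[i], ix, iy, w, denom)
        v1 = self._sample_snapshot(arr[i + 1], ix, iy, w, denom)
        return (1 - a) * v0 + a * v1


@dataclass
class Scenario:
    """A complete forcing bundle: bathymetry, field series, kelp raster."""

    bathymetry: BathymetryGrid
    fields: FieldSeries
    kelp_prob: np.ndarray

    def __post_init__(self) -> None:
        self.kelp_prob = np.asarray(self.kelp_prob, dtype=float)
        if self.kelp_prob.shape != self.bathymetry.shape:
            raise FieldValidationError("kelp_prob shape does not match grid")


# -- transects ------------------------------------------------------------


def cross_shore_transect(
    fields: FieldSeries,
    bathymetry: BathymetryGrid,
    alongshore_position: float,
    when,
    shelf_edge_depth: float = 200.0,
):
    """Sample bottom density along a coast-to-shelf-edge transect.

    The coast is on the low-x side of the grid.  Returns three aligned
    arrays ``(distance_m, rho_bottom, depth_m)`` covering every wet node of
    the nearest alongshore row with depth <= ``shelf_edge_depth``, ordered
    moving offshore; distances are measured from the last land node (or the
    domain edge if the whole row is wet).
    """
    y = np.asarray(bathymetry.y)
    if not (y[0] <= alongshore_position <= y[-1]):
        raise OutOfDomainError("alongshore position outside domain")
    j = int(np.argmin(np.abs(y - alongshore_position)))
    wet = bathymetry.wet[j]
    if not wet.any():
        raise OutOfWaterError("transect row is entirely land")
    sel = wet & (bathymetry.depth[j] <= shelf_edge_depth)
    if not sel.any():
        raise OutOfWaterError("no wet shelf nodes on transect row")
    land_idx = np.nonzero(~wet)[0]
    x_coast = bathymetry.x[land_idx.max()] if land_idx.size else bathymetry.x[0]
    i, a = fields._bracket(fields.seconds_of(when))
    rho_row = (1 - a) * fields.rho_bottom[i, j] + a * fields.rho_bottom[i + 1, j]
    mx, _ = bathymetry.metric_factors(y[j])
    dist = (bathymetry.x[sel] - x_coast) * float(mx)
    return dist, np.asarray(rho_row[sel], dtype=float), bathymetry.depth[j, sel]


# -- NetCDF I/O -----------------------------------------------------------

_REQUIRED_VARS = ("depth", "land_mask", "u_bottom", "v_bottom", "rho_bottom",
                  "wind_speed", "wind_dir")


def scenario_to_dataset(scenario: Scenario) -> xr.Dataset:
    """CF-style dataset mirror of a :class:`Scenario`."""
    b, f = scenario.bathymetry, scenario.fields
    coords = {
        "time": ("time", f.time),
        "y": ("y", b.y, {"units": "degrees_north" if b.geographic else "m"}),
        "x": ("x", b.x, {"units": "degrees_east" if b.geographic else "m"}),
    }
    data = {
        "depth": (("y", "x"), b.depth, {"units": "m", "positive": "down"}),
        "land_mask": (("y", "x"), b.land.astype("i1")),
        "u_bottom": (("time", "y", "x"), f.u, {"units": "m s-1"}),
        "v_bottom": (("time", "y", "x"), f.v, {"units": "m s-1"}),
        "rho_bottom": (("time", "y", "x"), f.rho_bottom, {"units": "kg m-3"}),
        "wind_speed": (("time", "y", "x"), f.wind_speed, {"units": "m s-1"}),
        "wind_dir": (("time", "y", "x"), f.wind_dir,
                     {"units": "degree", "comment": "direction wind comes from, clockwise from north"}),
        "kelp_prob": (("y", "x"), scenario.kelp_prob),
    }
    if f.rho_profile is not None:
        coords["layer"] = ("layer", f.profile_levels,
                           {"comment": "fractional height above bed (0=bed, 1=surface)"})
        data["rho_profile"] = (("time", "layer", "y", "x"), f.rho_profile,
                               {"units": "kg m-3"})
    ds = xr.Dataset(data, coords=coords)
    ds.attrs["geographic"] = int(b.geographic)
    return ds


def save_scenario(path, scenario: Scenario) -> None:
    """Write a scenario as NetCDF3 (scipy backend) so synthetic and real
    forcing enter the pipeline through the same reader."""
    ds = scenario_to_dataset(scenario)
    ds.to_netcdf(Path(path), engine="scipy")


def _extract_bottom_layer(da: xr.DataArray, ds: xr.Dataset) -> xr.DataArray:
    """Deepest layer of a (time, layer, y, x) variable.

    Uses the ``layer_depth`` coordinate when present (greatest depth wins),
    otherwise takes the last layer index.
    """
    if "layer_depth" in ds:
        k = int(np.argmax(np.asarray(ds["layer_depth"])))
    else:
        k = da.sizes["layer"] - 1
    return da.isel(layer=k)


def dataset_to_scenario(ds: xr.Dataset, rename: dict[str, str] | None = None) -> Scenario:
    if rename:
        ds = ds.rename({v: k for k, v in rename.items() if v in ds})
    for name in _REQUIRED_VARS:
        if name not in ds:
            raise FieldValidationError(f"forcing file is missing variable {name!r}")
    for ax in ("x", "y", "time"):
        if ax not in ds.coords and ax not in ds.dims:
            raise FieldValidationError(f"forcing file is missing coordinate {ax!r}")
    geographic = bool(ds.attrs.get("geographic", 0))
    bathy = BathymetryGrid(
        x=np.asarray(ds["x"]),
        y=np.asarray(ds["y"]),
        depth=np.asarray(ds["depth"], dtype=float),
        land=np.asarray(ds["land_mask"]).astype(bool),
        geographic=geographic,
    )
    u = ds["u_bottom"]
    v = ds["v_bottom"]
    if "layer" in u.dims:
        u = _extract_bottom_layer(u, ds)
        v = _extract_bottom_layer(v, ds)
    rho_profile = None
    levels = None
    if "rho_profile" in ds:
        rho_profile = np.asarray(ds["rho_profile"])
        levels = np.asarray(ds["layer"], dtype=float)
    fields = FieldSeries(
        grid=bathy,
        time=np.asarray(ds["time"]),
        u=np.nan_to_num(np.asarray(u)),
        v=np.nan_to_num(np.asarray(v)),
        rho_bottom=np.asarray(ds["rho_bottom"]),
        wind_speed=np.asarray(ds["wind_speed"]),
        wind_dir=np.asarray(ds["wind_dir"]),
        rho_profile=rho_profile,
        profile_levels=levels,
    )
    kelp = np.asarray(ds["kelp_prob"], dtype=float) if "kelp_prob" in ds else np.zeros(bathy.shape)
    return Scenario(bathymetry=bathy, fields=fields, kelp_prob=kelp)


def load_scenario(path, rename: dict[str, str] | None = None) -> Scenario:
    """Read a scenario file written by :func:`save_scenario` (or a foreign
    file with a ``rename`` mapping from our names to its variable names)."""
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        return dataset_to_scenario(ds.load(), rename=rename)


def load_fields(path, rename: dict[str, str] | None = None) -> FieldSeries:
    """Read just the forcing series (grid attached) from a scenario file."""
    return load_scenario(path, rename=rename).fields
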