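"""Digital elevation models: gridding, orientation, spike cleaning.

A DEM is a regular grid of surface heights (µm) interpolated from scattered
profilometer samples by piecewise-linear (barycentric) interpolation over a
Delaunay triangulation.  Nodes outside the convex hull of the measured (x, y)
positions are unmeasured; missingness is an explicit boolean mask, never a
magic elevation value.

Grid convention: ``grid[row, col]`` with rows along +y and columns along +x,
so node (i, j) sits at ``origin + (j * pitch, i * pitch)``.  ``occlusal_axis``
records which axis-aligned direction points toward the cusp ("row+", "row-",
"col+" or "col-").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .exceptions import DegenerateGeometryError, ParameterError
from .surface_io import PointCloud

__all__ = [
    "DEM",
    "interpolate_dem",
    "flip_vertical",
    "reduce_noise",
    "measured_fraction",
    "write_dem",
    "read_dem",
]

_AXES = ("row+", "row-", "col+", "col-")


@dataclass
class DEM:
    """Regular elevation grid in µm with an explicit measured-cell mask."""

    grid: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)
    occlusal_axis: str = "row-"
    mask: np.ndarray | None = None  # True where measured
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or min(self.grid.shape) < 2:
            raise ParameterError("DEM grid needs at least 2 rows and 2 columns")
        if not self.pixel_pitch > 0:
            raise ParameterError("pixel_pitch must be > 0")
        if self.occlusal_axis not in _AXES:
            raise ParameterError(f"occlusal_axis must be one of {_AXES}")
        if self.mask is None:
            self.mask = np.isfinite(self.grid)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ParameterError("mask shape must match grid shape")
        if not np.isfinite(self.grid[self.mask]).all():
            raise ParameterError("measured cells must hold finite elevations")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.grid.shape[1]) * self.pixel_pitch

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.grid.shape[0]) * self.pixel_pitch

    def masked_grid(self) -> np.ndarray:
        """Grid copy with NaN at unmeasured cells."""
        g = self.grid.copy()
        g[~self.mask] = np.nan
        return g


def interpolate_dem(
    cloud: PointCloud,
    pixel_pitch: float = 0.64,
    occlusal_axis: str = "row-",
) -> DEM:
    """Grid a point cloud by linear interpolation over its Delaunay triangulation.

    The grid spans the bounding box of the measured points.  Nodes inside the
    convex hull of the measured (x, y) positions receive the barycentric
    interpolant; nodes outside are unmeasured.  A node coincident with an
    input point reproduces its z exactly (the linear interpolant passes
    through the data).

    Exact duplicate (x, y) positions keep the last-read z with a warning.
    """
    if not pixel_pitch > 0:
        raise ParameterError("pixel_pitch must be > 0")
    pts = cloud.points[cloud.measured]
    xy = pts[:, :2]
    z = pts[:, 2]
    # deduplicate exact (x, y) repeats, keeping the last-read value
    _, inverse = np.unique(xy, axis=0, return_inverse=True)
    if inverse.max() + 1 < len(xy):
        warnings.warn(
            "duplicate (x, y) positions in point cloud; keeping last-read z",
            stacklevel=2,
        )
        keep_last = np.full(inverse.max() + 1, -1, dtype=int)
        keep_last[inverse] = np.arange(len(xy))  # later indices overwrite
        xy, z = xy[keep_last], z[keep_last]

    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    nx = int(np.floor((xmax - xmin) / pixel_pitch + 1e-9)) + 1
    ny = int(np.floor((ymax - ymin) / pixel_pitch + 1e-9)) + 1
    if nx < 2 or ny < 2:
        raise ParameterError("pixel_pitch too coarse for the cloud extent")
    try:
        interp = LinearNDInterpolator(xy, z)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"cannot triangulate point cloud (collinear input?): {exc}"
        ) from None
    gx = xmin + np.arange(nx) * pixel_pitch
    gy = ymin + np.arange(ny) * pixel_pitch
    X, Y = np.meshgrid(gx, gy)
    vals = interp(X, Y)
    return DEM(
        grid=vals,
        pixel_pitch=pixel_pitch,
        origin=(float(xmin), float(ymin)),
        occlusal_axis=occlusal_axis,
        mask=np.isfinite(vals),
        provenance=[f"interpolate_dem(source={cloud.source_id!r}, pitch={pixel_pitch})"],
    )


_FLIP = {"row+": "row-", "row-": "row+", "col+": "col+", "col-": "col-"}


def flip_vertical(dem: DEM) -> DEM:
    """Reverse the grid rows, updating the occlusal direction consistently.

    Profilometer exports read into row-major rasters come out upside-down;
    applying the flip twice returns the original DEM.
    """
    return DEM(
        grid=dem.grid[::-1].copy(),
        pixel_pitch=dem.pixel_pitch,
        origin=dem.origin,
        occlusal_axis=_FLIP[dem.occlusal_axis],
        mask=dem.mask[::-1].copy(),
        provenance=dem.provenance + ["flip_vertical"],
    )


def reduce_noise(dem: DEM, window: int = 5, k: float = 3.0) -> DEM:
    """Replace spike outliers by their local window median.

    A cell is an outlier when it deviates from the median of its
    ``window x window`` neighbourhood by more than ``k`` robust standard
    deviations (1.4826 x the window median absolute deviation).  Unmeasured
    cells are ignored in the window statistics and stay unmeasured.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 3")
    if not k > 0:
        raise ParameterError("k must be > 0")
    if window > min(dem.shape):
        raise ParameterError(
            f"window {window} exceeds grid dimensions {dem.shape}"
        )
    g = dem.masked_grid()
    pad = window // 2
    padded = np.pad(g, pad, mode="constant", constant_values=np.nan)
    win = sliding_window_view(padded, (window, window))
    flat = win.reshape(g.shape[0], g.shape[1], window * window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(flat, axis=-1)
        mad = np.nanmedian(np.abs(flat - med[..., None]), axis=-1)
    dev = np.abs(g - med)
    spike = dem.mask & np.isfinite(med) & (dev > k * 1.4826 * mad)
    out = dem.grid.copy()
    out[spike] = med[spike]
    return DEM(
        grid=out,
        pixel_pitch=dem.pixel_pitch,
        origin=dem.origin,
        occlusal_axis=dem.occlusal_axis,
        mask=dem.mask.copy(),
        provenance=dem.provenance + [f"reduce_noise(window={window}, k={k})"],
    )


def measured_fraction(obj: PointCloud | DEM) -> float:
    """Measured count over total count, in [0, 1]."""
    if isinstance(obj, DEM):
        return float(obj.mask.mean())
    return float(obj.measured.mean())


def write_dem(dem: DEM, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Export grid as CSV (NaN = unmeasured) plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    np.savetxt(csv_path, dem.masked_grid(), delimiter=",", fmt="%.10g")
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(csv_path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_pitch_um": dem.pixel_pitch,
                "origin_um": list(dem.origin),
                "occlusal_axis": dem.occlusal_axis,
                "provenance": dem.provenance,
            },
            indent=2,
        )
    )


def read_dem(csv_path: str | Path, sidecar_path: str | Path | None = None) -> DEM:
    csv_path = Path(csv_path)
    grid = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(csv_path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return DEM(
        grid=grid,
        pixel_pitch=meta["pixel_pitch_um"],
        origin=tuple(meta["origin_um"]),
        occlusal_axis=meta["occlusal_axis"],
        mask=np.isfinite(grid),
        provenance=list(meta.get("provenance", [])),
    )
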