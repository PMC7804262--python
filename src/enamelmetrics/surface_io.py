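"""Read/write point clouds, elevation grids and measurement tables.

Confocal profilometers export surface topographies as plain-text ``.dat``
files with one (x, y, z) sample per line, in micrometres.  Unmeasured points
(dropouts where the instrument collected no valid height) are encoded with a
no-data token in the z field; they are kept, flagged as unmeasured, and never
silently dropped, so the measured-point fraction reported by the instrument
remains computable downstream.

All lengths inside the package are micrometres.  Unit conversion happens only
here, at the I/O boundary.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, IntegrityError, MalformedInputError, ParameterError

__all__ = [
    "PointCloud",
    "ScanMetadata",
    "read_xyz_dat",
    "write_xyz_dat",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]

#: µm per unit for the length units accepted at I/O boundaries.
UNIT_TO_UM = {
    "um": 1.0,
    "µm": 1.0,  # µm
    "μm": 1.0,  # μm (greek mu)
    "micron": 1.0,
    "microns": 1.0,
    "mm": 1000.0,
    "cm": 1.0e4,
    "m": 1.0e6,
    "nm": 1.0e-3,
}

#: Default z-field tokens that mark an unmeasured point.
DEFAULT_NO_DATA_TOKENS = ("", "nan", "na", "*", "---")


def _collinear(xy: np.ndarray) -> bool:
    """True if all (x, y) positions lie on one line (or fewer than 3 points)."""
    if len(xy) < 3:
        return True
    centered = xy - xy.mean(axis=0)
    # rank < 2 means all positions are collinear in the plane
    return np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(xy).max())) < 2


@dataclass
class PointCloud:
    """Raw (x, y, z) surface samples in µm with acquisition metadata.

    ``points`` is an (n, 3) float array.  z is NaN for unmeasured points,
    whose positions are still meaningful; ``measured`` flags them.
    """

    points: np.ndarray
    source_id: str = ""
    lateral_pitch: float | None = None
    z_step: float | None = None
    measured: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError("points must be an (n, 3) array")
        if self.measured is None:
            self.measured = np.isfinite(self.points[:, 2])
        else:
            self.measured = np.asarray(self.measured, dtype=bool)
            if self.measured.shape != (len(self.points),):
                raise ParameterError("measured flags must match point count")
        if not np.isfinite(self.points[:, :2]).all():
            raise MalformedInputError("x/y coordinates must be finite")
        if not np.isfinite(self.points[self.measured, 2]).all():
            raise MalformedInputError("measured points must have finite z")
        for name in ("lateral_pitch", "z_step"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        if _collinear(self.points[self.measured, :2]):
            raise MalformedInputError(
                "need at least 3 non-collinear measured (x, y) positions"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def measured_fraction(self) -> float:
        return float(self.measured.mean())


@dataclass
class ScanMetadata:
    """Acquisition settings of one confocal scan field.

    pixel_pitch and z_step in µm; field_of_view is (width, length) in µm.
    """

    pixel_pitch: float = 0.64
    z_step: float = 1.0
    z_range: float | None = None
    field_of_view: tuple[float, float] | None = None
    measured_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.pixel_pitch > 0:
            raise ParameterError("pixel_pitch must be > 0")
        if not self.z_step > 0:
            raise ParameterError("z_step must be > 0")
        if self.measured_fraction is not None and not (
            0.0 <= self.measured_fraction <= 1.0
        ):
            raise ParameterError("measured_fraction must be within [0, 1]")

    def to_json(self, path: str | Path) -> None:
        d = {
            "pixel_pitch_um": self.pixel_pitch,
            "z_step_um": self.z_step,
            "z_range_um": self.z_range,
            "field_of_view_um": list(self.field_of_view) if self.field_of_view else None,
            "measured_fraction": self.measured_fraction,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanMetadata":
        d = json.loads(Path(path).read_text())
        fov = d.get("field_of_view_um")
        return cls(
            pixel_pitch=d["pixel_pitch_um"],
            z_step=d["z_step_um"],
            z_range=d.get("z_range_um"),
            field_of_view=tuple(fov) if fov else None,
            measured_fraction=d.get("measured_fraction"),
        )


def _detect_delimiter(line: str) -> str:
    if ";" in line:
        return ";"
    if "," in line:
        return ","
    return " "


def read_xyz_dat(
    source,
    units: str = "um",
    column_order: Sequence[str] = ("x", "y", "z"),
    no_data_tokens: Iterable[str] = DEFAULT_NO_DATA_TOKENS,
    source_id: str = "",
    lateral_pitch: float | None = None,
    z_step: float | None = None,
) -> PointCloud:
    """Parse a delimited-text XYZ export into a :class:`PointCloud`.

    The delimiter (whitespace, comma or semicolon) is auto-detected from the
    first data line and must be consistent throughout the file.  Lines whose
    z field matches a no-data token become unmeasured points.  Coordinates
    are converted to µm according to ``units``.

    Parameters
    ----------
    source:
        Path, or an open text stream.
    units:
        Length unit of the numeric literals in the file (default µm).
    column_order:
        Permutation of ("x", "y", "z") giving the column meaning.
    """
    try:
        scale = UNIT_TO_UM[units.lower()]
    except KeyError:
        raise ParameterError(f"unknown length unit {units!r}") from None
    order = tuple(column_order)
    if sorted(order) != ["x", "y", "z"]:
        raise ParameterError("column_order must be a permutation of x, y, z")
    col = {name: order.index(name) for name in "xyz"}
    tokens = {t.lower() for t in no_data_tokens}

    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if not source_id:
            source_id = str(source)
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)

    delim: str | None = None
    pts: list[tuple[float, float, float]] = []
    flags: list[bool] = []
    first_bad: tuple[int, str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if delim is None:
            delim = _detect_delimiter(line)
        else:
            for other in (";", ","):
                if other != delim and other in line:
                    raise FormatError(
                        f"mixed delimiters: line {lineno} contains {other!r} "
                        f"but the file uses {delim!r}"
                    )
        if delim == " ":
            fields = line.split()
        else:
            fields = [f.strip() for f in line.split(delim)]
            # tolerate whitespace-padded delimited fields but not extra columns
        if len(fields) != 3:
            if first_bad is None:
                first_bad = (lineno, raw)
            continue
        try:
            x = float(fields[col["x"]])
            y = float(fields[col["y"]])
        except ValueError:
            if first_bad is None:
                first_bad = (lineno, raw)
            continue
        zf = fields[col["z"]]
        if zf.lower() in tokens:
            pts.append((x * scale, y * scale, np.nan))
            flags.append(False)
            continue
        try:
            z = float(zf)
        except ValueError:
            if first_bad is None:
                first_bad = (lineno, raw)
            continue
        pts.append((x * scale, y * scale, z * scale))
        flags.append(True)

    if sum(flags) < 3:
        where = f" (first offending line {first_bad[0]}: {first_bad[1]!r})" if first_bad else ""
        raise MalformedInputError(
            f"fewer than 3 valid measured points parsed{where}"
        )
    if first_bad is not None:
        warnings.warn(
            f"skipped unparseable line(s); first at line {first_bad[0]}: {first_bad[1]!r}",
            stacklevel=2,
        )
    return PointCloud(
        points=np.array(pts, dtype=float),
        source_id=source_id,
        lateral_pitch=lateral_pitch,
        z_step=z_step,
        measured=np.array(flags, dtype=bool),
    )


def write_xyz_dat(
    cloud: PointCloud,
    path: str | Path,
    units: str = "um",
    delimiter: str = " ",
    no_data_token: str = "NaN",
    fmt: str = "%.6g",
) -> None:
    """Write a point cloud back to delimited text (inverse of read_xyz_dat)."""
    scale = UNIT_TO_UM[units.lower()]
    lines = []
    for (x, y, z), ok in zip(cloud.points, cloud.measured):
        zf = fmt % (z / scale) if ok else no_data_token
        lines.append(delimiter.join((fmt % (x / scale), fmt % (y / scale), zf)))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Measurement tables

MEASUREMENT_COLUMNS = [
    "specimen",
    "taxon",
    "site",
    "group",
    "tooth_type",
    "feature_kind",
    "feature_id",
    "replicate",
    "depth_um",
    "transect_x0",
    "transect_y0",
    "transect_x1",
    "transect_y1",
]


def write_measurements(records: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write one CSV row per depth measurement replicate.

    Raises IntegrityError on duplicate (feature_id, replicate) pairs so that
    the triplicate structure of the protocol stays auditable.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise IntegrityError("no measurement records to write")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"measurement records missing columns: {missing}")
    dup = df.duplicated(subset=["feature_id", "replicate"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["feature_id", "replicate"]].tolist()
        raise IntegrityError(f"duplicate (feature_id, replicate) pair: {pair}")
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"measurement table missing columns: {missing}")
    numeric = ["depth_um", "transect_x0", "transect_y0", "transect_x1", "transect_y1"]
    df[numeric] = df[numeric].astype(float)
    return df
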