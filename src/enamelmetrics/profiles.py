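"""Transect definition and 2-D profile extraction from a DEM.

A transect is a straight segment drawn orthogonal to the features of
interest — across the occlusal shoulders of a defect, or across several
perikymata.  Profiles are sampled bilinearly at equal spacing along the
segment and re-ordered so the occlusal end sits at distance 0, matching the
convention that depths are measured from the occlusal side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dem import DEM
from .exceptions import GeometryError, ParameterError, UnusableTransectError

__all__ = ["Transect", "Profile2D", "extract_profile", "replicate_transects"]


@dataclass
class Transect:
    """Straight segment in DEM coordinates (µm)."""

    start: tuple[float, float]
    end: tuple[float, float]
    sampling_step: float | None = None  # default: DEM pixel pitch
    occlusal_end: Literal["start", "end"] = "start"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ParameterError("transect must have positive length")
        if self.sampling_step is not None and not self.sampling_step > 0:
            raise ParameterError("sampling_step must be > 0")
        if self.occlusal_end not in ("start", "end"):
            raise ParameterError("occlusal_end must be 'start' or 'end'")

    @property
    def length(self) -> float:
        dx = self.end[0] - self.start[0]
        dy = self.end[1] - self.start[1]
        return float(np.hypot(dx, dy))

    def to_json(self) -> str:
        return json.dumps(
            {
                "start_um": list(self.start),
                "end_um": list(self.end),
                "sampling_step_um": self.sampling_step,
                "occlusal_end": self.occlusal_end,
            }
        )

    @classmethod
    def from_json(cls, s: str | dict) -> "Transect":
        d = json.loads(s) if isinstance(s, str) else s
        return cls(
            start=tuple(d["start_um"]),
            end=tuple(d["end_um"]),
            sampling_step=d.get("sampling_step_um"),
            occlusal_end=d.get("occlusal_end", "start"),
        )


@dataclass
class Profile2D:
    """Ordered (distance, elevation) samples; occlusal end at distance 0."""

    distance: np.ndarray
    elevation: np.ndarray
    measured: np.ndarray
    transect: Transect | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.measured is None:
            self.measured = np.isfinite(self.elevation)
        self.measured = np.asarray(self.measured, dtype=bool)
        if not (
            len(self.distance) == len(self.elevation) == len(self.measured)
        ):
            raise ParameterError("profile arrays must have equal length")
        d = self.distance
        if d[0] != 0 or np.any(np.diff(d) <= 0):
            raise ParameterError("distances must increase strictly from 0")

    def __len__(self) -> int:
        return len(self.distance)


def extract_profile(dem: DEM, transect: Transect) -> Profile2D:
    """Sample the DEM bilinearly at equal spacing along a transect.

    Samples landing on (or next to) unmeasured cells are flagged unmeasured
    and excluded from extremum search downstream.  More than 20% unmeasured
    samples, or an unmeasured endpoint, makes the transect unusable.
    """
    step = transect.sampling_step or dem.pixel_pitch
    n = max(2, int(round(transect.length / step)) + 1)
    t = np.linspace(0.0, 1.0, n)
    xs = transect.start[0] + t * (transect.end[0] - transect.start[0])
    ys = transect.start[1] + t * (transect.end[1] - transect.start[1])
    interp = RegularGridInterpolator(
        (dem.y_coords, dem.x_coords),
        dem.masked_grid(),
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    elev = interp(np.column_stack([ys, xs]))
    ok = np.isfinite(elev)
    if not (ok[0] and ok[-1]):
        raise UnusableTransectError("transect endpoint lies outside the measured extent")
    frac_missing = 1.0 - ok.mean()
    if frac_missing > 0.20:
        raise UnusableTransectError(
            f"{100 * frac_missing:.1f}% of transect samples fall on unmeasured cells"
        )
    dist = t * transect.length
    if transect.occlusal_end == "end":
        elev = elev[::-1]
        ok = ok[::-1]
    prof = Profile2D(
        distance=dist,
        elevation=elev,
        measured=ok,
        transect=transect,
        provenance=dem.provenance + ["extract_profile"],
    )
    if len(prof) < 8:
        raise UnusableTransectError("profile has fewer than 8 samples")
    return prof


def replicate_transects(
    base: Transect, n: int = 3, lateral_offset: float = 25.0, dem: DEM | None = None
) -> list[Transect]:
    """Build n parallel transects centered on the base.

    Defect depth is measured in triplicate on separate parallel transects;
    the default lateral offset of 25 µm keeps replicates within a single
    defect's lateral extent.  When a DEM is given, offsets that push a
    transect off the grid raise :class:`GeometryError`.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if n > 1 and not lateral_offset > 0:
        raise ParameterError("lateral_offset must be > 0")
    dx = base.end[0] - base.start[0]
    dy = base.end[1] - base.start[1]
    length = base.length
    # unit normal, left of the direction of travel
    nxv, nyv = -dy / length, dx / length
    out: list[Transect] = []
    for i in range(n):
        off = (i - (n - 1) / 2.0) * lateral_offset
        tr = Transect(
            start=(base.start[0] + off * nxv, base.start[1] + off * nyv),
            end=(base.end[0] + off * nxv, base.end[1] + off * nyv),
            sampling_step=base.sampling_step,
            occlusal_end=base.occlusal_end,
        )
        if dem is not None:
            for px, py in (tr.start, tr.end):
                if not (
                    dem.x_coords[0] <= px <= dem.x_coords[-1]
                    and dem.y_coords[0] <= py <= dem.y_coords[-1]
                ):
                    raise GeometryError(
                        f"replicate offset {off:+.1f} µm pushes the transect off the DEM"
                    )
        out.append(tr)
    return out


def shoulder_level_check(
    profile: Profile2D, expected_depth: float, tolerance_fraction: float = 0.25
) -> bool:
    """Quality check that the two profile ends are level.

    Transects should be placed where the surface is level on either side of
    the target feature.  Returns True when the end-elevation difference stays
    below ``tolerance_fraction`` of the expected depth; otherwise warns and
    returns False.
    """
    diff = abs(float(profile.elevation[0]) - float(profile.elevation[-1]))
    if diff > tolerance_fraction * expected_depth:
        warnings.warn(
            f"transect shoulders differ by {diff:.2f} µm "
            f"(> {tolerance_fraction:.0%} of expected depth {expected_depth:.2f} µm)",
            stacklevel=2,
        )
        return False
    return True
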