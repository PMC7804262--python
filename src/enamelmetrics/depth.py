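"""Extremum detection and depth measurement on 2-D profiles.

Depth conventions
-----------------
Defect depth is the maximum difference between the occlusal shoulder and the
deepest point within the groove.  Perikyma depth is the maximum difference
between a perikyma groove and its occlusal-side perikyma ridge.  Both use the
occlusal reference for consistency; the cervical shoulder elevation is kept
for audit but never used.

Extremum detection mirrors amplitude-threshold peak pickers used on such
profiles: all strict local extrema are found (plateaus collapse to a single
extremum at the plateau midpoint), then adjacent maximum–minimum pairs are
pruned smallest-amplitude-first until every adjacent pair spans at least the
minimum amplitude.  No smoothing is applied; spike noise is assumed to have
been cleaned on the DEM beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import AggregationError, NoDefectFoundError, ParameterError
from .profiles import Profile2D, Transect

__all__ = [
    "PeakSet",
    "DepthMeasurement",
    "FeatureSummary",
    "find_extrema",
    "measure_defect_depth",
    "measure_perikymata_depths",
    "aggregate_feature",
]

DEFAULT_DEFECT_AMPLITUDE = 5.0  # µm; between perikymata and defect depth regimes
DEFAULT_PERIKYMATA_AMPLITUDE = 0.2  # µm; below typical perikymata depths


@dataclass
class PeakSet:
    """Retained alternating local maxima and minima of a profile."""

    maxima: list[tuple[float, float]]  # (distance, elevation)
    minima: list[tuple[float, float]]
    min_amplitude: float

    def ordered(self) -> list[tuple[float, float, str]]:
        """All retained extrema in transect order, tagged 'max'/'min'."""
        items = [(d, z, "max") for d, z in self.maxima] + [
            (d, z, "min") for d, z in self.minima
        ]
        return sorted(items, key=lambda it: it[0])


@dataclass
class DepthMeasurement:
    """One defect or perikyma depth with its shoulder and floor positions."""

    feature_kind: Literal["defect", "perikyma"]
    depth: float  # µm
    shoulder: tuple[float, float]  # (distance, elevation), occlusal reference
    floor: tuple[float, float]
    replicate_index: int = 0
    transect: Transect | None = None
    convention: str = "occlusal_shoulder"
    cervical_shoulder: tuple[float, float] | None = None  # audit only

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise ParameterError("depth must be > 0")
        if not np.isclose(self.depth, self.shoulder[1] - self.floor[1]):
            raise ParameterError("depth must equal shoulder minus floor elevation")


def _collapse_plateaus(
    distance: np.ndarray, elevation: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs of exactly equal consecutive elevations into midpoints."""
    if len(elevation) == 0:
        return distance, elevation
    keep_d: list[float] = []
    keep_z: list[float] = []
    i = 0
    n = len(elevation)
    while i < n:
        j = i
        while j + 1 < n and elevation[j + 1] == elevation[i]:
            j += 1
        keep_d.append(0.5 * (distance[i] + distance[j]))
        keep_z.append(float(elevation[i]))
        i = j + 1
    return np.asarray(keep_d), np.asarray(keep_z)


def _local_extrema(d: np.ndarray, z: np.ndarray) -> list[tuple[float, float, str]]:
    """Strict interior extrema of a plateau-free sequence, in order."""
    out: list[tuple[float, float, str]] = []
    for i in range(1, len(z) - 1):
        if z[i] > z[i - 1] and z[i] > z[i + 1]:
            out.append((float(d[i]), float(z[i]), "max"))
        elif z[i] < z[i - 1] and z[i] < z[i + 1]:
            out.append((float(d[i]), float(z[i]), "min"))
    return out


def find_extrema(profile: Profile2D, min_amplitude: float) -> PeakSet:
    """Locate local extrema and prune below-amplitude pairs.

    Works on measured samples only.  Pruning removes the adjacent
    extremum pair of smallest elevation difference, repeatedly, until every
    adjacent retained pair spans at least ``min_amplitude``; ties break on
    the earlier (more occlusal) pair for determinism.
    """
    if min_amplitude < 0:
        raise ParameterError("min_amplitude must be >= 0")
    d_all = profile.distance[profile.measured]
    z_all = profile.elevation[profile.measured]
    if len(d_all) < 8:
        raise ParameterError("profile must have at least 8 measured samples")
    d, z = _collapse_plateaus(d_all, z_all)
    ext = _local_extrema(d, z)
    # smallest-amplitude-first pair pruning
    while len(ext) >= 2:
        amps = [abs(ext[i + 1][1] - ext[i][1]) for i in range(len(ext) - 1)]
        i = int(np.argmin(amps))
        if amps[i] >= min_amplitude:
            break
        del ext[i : i + 2]
    maxima = [(dd, zz) for dd, zz, kind in ext if kind == "max"]
    minima = [(dd, zz) for dd, zz, kind in ext if kind == "min"]
    return PeakSet(maxima=maxima, minima=minima, min_amplitude=min_amplitude)


def _occlusal_reference(
    profile: Profile2D, peaks: PeakSet, floor_d: float
) -> tuple[float, float]:
    """Occlusal-side reference maximum for a floor at distance ``floor_d``.

    Nearest retained maximum occlusal of the floor; when none is retained
    (e.g. the shoulder sits at the profile edge with no interior maximum),
    fall back to the highest measured sample occlusal of the floor.
    """
    occl = [(dd, zz) for dd, zz in peaks.maxima if dd < floor_d]
    if occl:
        return occl[-1]  # nearest occlusal retained maximum
    m = profile.measured & (profile.distance < floor_d)
    if not m.any():
        raise NoDefectFoundError("no occlusal samples available for the shoulder")
    i = int(np.argmax(np.where(m, profile.elevation, -np.inf)))
    return float(profile.distance[i]), float(profile.elevation[i])


def measure_defect_depth(
    profile: Profile2D,
    min_amplitude: float = DEFAULT_DEFECT_AMPLITUDE,
    replicate_index: int = 0,
) -> DepthMeasurement:
    """Maximum defect depth from the occlusal side of the defect.

    The floor is the deepest minimum surviving amplitude thresholding; the
    shoulder is the occlusal-side maximum.  The profile is expected to span
    both occlusal shoulders of exactly one target defect.
    """
    peaks = find_extrema(profile, min_amplitude)
    if not peaks.minima:
        raise NoDefectFoundError(
            "no groove minimum survives thresholding "
            f"(min_amplitude={min_amplitude} µm too high, or no defect present)"
        )
    floor = min(peaks.minima, key=lambda p: p[1])
    shoulder = _occlusal_reference(profile, peaks, floor[0])
    cervical = [(dd, zz) for dd, zz in peaks.maxima if dd > floor[0]]
    depth = shoulder[1] - floor[1]
    if not depth > 0:
        raise NoDefectFoundError("occlusal shoulder does not rise above the floor")
    return DepthMeasurement(
        feature_kind="defect",
        depth=float(depth),
        shoulder=shoulder,
        floor=floor,
        replicate_index=replicate_index,
        transect=profile.transect,
        cervical_shoulder=cervical[0] if cervical else None,
    )


def measure_perikymata_depths(
    profile: Profile2D,
    n_target: int | None = 10,
    min_amplitude: float = DEFAULT_PERIKYMATA_AMPLITUDE,
) -> list[DepthMeasurement]:
    """Depths of up to ``n_target`` perikyma grooves, in transect order.

    Each groove's depth is its occlusal-side adjacent ridge elevation minus
    the groove elevation.  A groove with no retained occlusal ridge (the
    first extremum of the profile) is skipped.  Fewer grooves than requested
    is a warning, not an error — preservation commonly limits the count.
    ``n_target=None`` measures every groove on the profile without warning.
    """
    if n_target is not None and n_target < 1:
        raise ParameterError("n_target must be >= 1")
    peaks = find_extrema(profile, min_amplitude)
    seq = peaks.ordered()
    out: list[DepthMeasurement] = []
    for i, (dd, zz, kind) in enumerate(seq):
        if kind != "min":
            continue
        if i == 0 or seq[i - 1][2] != "max":
            continue  # no occlusal-side ridge for this groove
        ridge = (seq[i - 1][0], seq[i - 1][1])
        out.append(
            DepthMeasurement(
                feature_kind="perikyma",
                depth=float(ridge[1] - zz),
                shoulder=ridge,
                floor=(dd, zz),
                replicate_index=len(out),
                transect=profile.transect,
            )
        )
        if n_target is not None and len(out) == n_target:
            break
    if n_target is not None and len(out) < n_target:
        warnings.warn(
            f"only {len(out)} of {n_target} requested perikymata measurable",
            stacklevel=2,
        )
    return out


@dataclass
class FeatureSummary:
    """Replicate aggregate; the mean is the feature's depth of record."""

    mean_depth: float
    n: int
    spread: float  # range (max - min) across replicates
    depth_range: tuple[float, float] = field(default=(0.0, 0.0))


def aggregate_feature(measurements: Sequence[DepthMeasurement]) -> FeatureSummary:
    """Arithmetic mean, count and range of replicate depths for one feature."""
    if not measurements:
        raise AggregationError("cannot aggregate an empty measurement set")
    kinds = {m.feature_kind for m in measurements}
    if len(kinds) > 1:
        raise AggregationError(f"mixed feature kinds in one aggregate: {kinds}")
    depths = np.array([m.depth for m in measurements], dtype=float)
    return FeatureSummary(
        mean_depth=float(depths.mean()),
        n=len(depths),
        spread=float(depths.max() - depths.min()),
        depth_range=(float(depths.min()), float(depths.max())),
    )
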