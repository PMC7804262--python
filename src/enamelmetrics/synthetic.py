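"""Synthetic tooth-surface topographies and measurement cohorts.

The generator emulates a midcrown enamel field as seen by a confocal
profilometer: a smooth crown form (cylindrical curvature along the
cuspo-cervical axis), quasi-periodic perikymata modelled as an asymmetric
ripple whose spacing tightens toward the cervix, one or more furrow-form
defects (Gaussian depressions spanning several perikymata; box-shaped
"plane-form" defects are available but not the default), plus Gaussian
measurement noise, occasional spike artifacts, and unmeasured dropouts.

Coordinate convention: y is the cuspo-cervical axis with the occlusal
(cuspal) side at y = 0; x runs mesiodistally.  Elevations are µm.

Ground truth carries two depths per feature: the *nominal* amplitude of the
feature component (form excluded), and the *surface* depth obtained by
applying the occlusal-shoulder measurement convention to a densely sampled,
noise-free profile of the full surface.  The surface depth is what a perfect
instrument would measure on the curved crown and is the reference for
pipeline-recovery checks; the nominal amplitude is the reference for
distribution-level checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .dem import DEM
from .depth import (
    DEFAULT_PERIKYMATA_AMPLITUDE,
    measure_defect_depth,
    measure_perikymata_depths,
)
from .exceptions import SpecError
from .profiles import Profile2D, Transect
from .surface_io import PointCloud

__all__ = [
    "PerikymataSpec",
    "DefectSpec",
    "SyntheticSurfaceSpec",
    "GroundTruth",
    "generate_surface",
    "clean_elevation",
    "feature_elevation",
    "defect_transect",
    "default_defect_amplitude",
    "nominal_groove_table",
    "reference_defect_depths",
    "reference_perikymata_depths",
    "GroupSpec",
    "CohortSpec",
    "generate_cohort",
]


@dataclass
class PerikymataSpec:
    """Quasi-periodic growth-increment ripple.

    mean_spacing: ridge-to-ridge distance at the occlusal edge (µm).
    spacing_gradient: fractional tightening of the spacing across the field
    toward the cervix (0 = uniform).
    depth_mean / depth_sd: per-groove depth distribution (µm).
    asymmetry: skews each groove cervically (0 = symmetric cosine).
    """

    mean_spacing: float = 45.0
    spacing_gradient: float = 0.15
    depth_mean: float = 1.5
    depth_sd: float = 0.3
    asymmetry: float = 0.3


@dataclass
class DefectSpec:
    """One furrow- or plane-form defect along the cuspo-cervical axis."""

    center: float  # µm from the occlusal edge
    width: float  # full width at half maximum, µm
    depth: float  # µm
    shape: Literal["gaussian_furrow", "box_plane"] = "gaussian_furrow"


@dataclass
class SyntheticSurfaceSpec:
    """Full description of one synthetic scan field."""

    extent: tuple[float, float] = (500.0, 1500.0)  # (width x, length y) µm
    pixel_pitch: float = 0.64
    crown_radius: float = 5000.0  # µm; math.inf = flat
    apex_position: float | None = None  # y of the curvature apex; default L/2
    perikymata: PerikymataSpec = field(default_factory=PerikymataSpec)
    defects: list[DefectSpec] = field(default_factory=list)
    noise_sd: float = 0.05
    spike_rate: float = 0.0005
    spike_amplitude: float = 50.0
    dropout_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        w, length = self.extent
        if not (w > 0 and length > 0 and self.pixel_pitch > 0):
            raise SpecError("extent and pixel_pitch must be positive")
        if not self.crown_radius > 0:
            raise SpecError("crown_radius must be > 0 (use math.inf for flat)")
        for rate in (self.spike_rate, self.dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise SpecError("rates must lie in [0, 1]")
        if self.noise_sd < 0 or self.spike_amplitude < 0:
            raise SpecError("noise_sd and spike_amplitude must be >= 0")
        pk = self.perikymata
        if not (pk.mean_spacing > 0 and pk.depth_mean > 0 and pk.depth_sd >= 0):
            raise SpecError("perikymata spacing and depths must be positive")
        if not 0.0 <= pk.spacing_gradient < 1.0:
            raise SpecError("spacing_gradient must be in [0, 1)")
        for d in self.defects:
            if not (d.depth > 0 and d.width > 0):
                raise SpecError("defect depth and width must be positive")
            if d.width <= pk.mean_spacing:
                raise SpecError(
                    "defect width must exceed the perikymata mean spacing"
                )
            if d.center - d.width < 0 or d.center + d.width > length:
                raise SpecError(
                    f"defect at y={d.center} µm (width {d.width}) extends beyond "
                    f"the {length} µm surface"
                )
        if math.isfinite(self.crown_radius):
            apex = self.apex if self.apex_position is None else self.apex_position
            if max(abs(0.0 - apex), abs(length - apex)) >= self.crown_radius:
                raise SpecError("field extends past the crown radius")

    @property
    def apex(self) -> float:
        return self.extent[1] / 2.0 if self.apex_position is None else self.apex_position


# ---------------------------------------------------------------------------
# Elevation components (deterministic functions of y)

def _groove_depths(spec: SyntheticSurfaceSpec, n: int) -> np.ndarray:
    """Per-groove depths, reproducible from the spec seed alone."""
    rng = np.random.default_rng([spec.seed % (2**31), 11])
    pk = spec.perikymata
    d = rng.normal(pk.depth_mean, pk.depth_sd, size=n)
    return np.clip(d, 0.2 * pk.depth_mean, None)


def _phase(spec: SyntheticSurfaceSpec, y: np.ndarray) -> np.ndarray:
    """Cumulative number of perikymata periods from the occlusal edge."""
    pk = spec.perikymata
    L = spec.extent[1]
    g = pk.spacing_gradient
    if g == 0:
        return y / pk.mean_spacing
    # local spacing s(y) = s0 (1 - g y / L); phase = integral of 1/s
    return -(L / (pk.mean_spacing * g)) * np.log1p(-g * y / L)


def _n_grooves(spec: SyntheticSurfaceSpec) -> int:
    return int(np.ceil(_phase(spec, np.array([spec.extent[1]]))[0])) + 2


def _ripple(spec: SyntheticSurfaceSpec, y: np.ndarray) -> np.ndarray:
    pk = spec.perikymata
    phi = _phase(spec, y)
    k = np.floor(phi).astype(int)
    t = phi - k
    depths = _groove_depths(spec, _n_grooves(spec))
    h = t ** (1.0 + pk.asymmetry)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * h))
    return -depths[np.clip(k, 0, len(depths) - 1)] * w


def _defect_component(spec: SyntheticSurfaceSpec, y: np.ndarray) -> np.ndarray:
    z = np.zeros_like(y, dtype=float)
    for d in spec.defects:
        if d.shape == "gaussian_furrow":
            sigma = d.width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            z -= d.depth * np.exp(-((y - d.center) ** 2) / (2.0 * sigma**2))
        elif d.shape == "box_plane":
            edge = 0.1 * d.width
            lo = 1.0 / (1.0 + np.exp(-(y - (d.center - d.width / 2)) / edge))
            hi = 1.0 / (1.0 + np.exp(-(y - (d.center + d.width / 2)) / edge))
            z -= d.depth * (lo - hi)
        else:  # pragma: no cover - guarded by the dataclass Literal
            raise SpecError(f"unknown defect shape {d.shape!r}")
    return z


def _form(spec: SyntheticSurfaceSpec, y: np.ndarray) -> np.ndarray:
    if math.isinf(spec.crown_radius):
        return np.zeros_like(y, dtype=float)
    r = spec.crown_radius
    return np.sqrt(r * r - (y - spec.apex) ** 2) - r


def feature_elevation(spec: SyntheticSurfaceSpec, y: np.ndarray) -> np.ndarray:
    """Feature component only (perikymata + defects), form excluded."""
    y = np.asarray(y, dtype=float)
    return _ripple(spec, y) + _defect_component(spec, y)


def clean_elevation(spec: SyntheticSurfaceSpec, y: np.ndarray) -> np.ndarray:
    """Noise-free full surface elevation (form + features) along y."""
    y = np.asarray(y, dtype=float)
    return _form(spec, y) + feature_elevation(spec, y)


# ---------------------------------------------------------------------------
# Reference (dense analytic) measurements

def _dense_profile(spec: SyntheticSurfaceSpec, y0: float, y1: float, step: float) -> Profile2D:
    n = max(9, int(round((y1 - y0) / step)) + 1)
    y = np.linspace(y0, y1, n)
    z = clean_elevation(spec, y)
    return Profile2D(
        distance=y - y0,
        elevation=z,
        measured=np.ones(n, dtype=bool),
        provenance=["dense_reference_profile"],
    )


def default_defect_amplitude(depth: float) -> float:
    """Amplitude threshold used for a defect of the given nominal depth.

    The standard 5 µm threshold separates defects from perikymata; for
    shallower defects the threshold drops to half the expected depth, the
    manual adjustment the protocol prescribes for shallow features.
    """
    return min(5.0, 0.5 * depth)


def defect_transect(
    spec: SyntheticSurfaceSpec, defect: DefectSpec, x: float | None = None,
    span_factor: float = 1.5,
) -> Transect:
    """Transect across one defect's occlusal shoulders, occlusal end first."""
    w, length = spec.extent
    x = w / 2.0 if x is None else x
    y0 = max(0.0, defect.center - span_factor * defect.width)
    y1 = min(length, defect.center + span_factor * defect.width)
    return Transect(start=(x, y0), end=(x, y1), occlusal_end="start")


def reference_defect_depths(spec: SyntheticSurfaceSpec, step: float | None = None) -> list[dict]:
    """Convention depths of each defect on the dense noise-free surface."""
    out = []
    step = step or spec.pixel_pitch / 4.0
    for d in spec.defects:
        tr = defect_transect(spec, d)
        prof = _dense_profile(spec, tr.start[1], tr.end[1], step)
        amp = default_defect_amplitude(d.depth)
        m = measure_defect_depth(prof, min_amplitude=amp)
        out.append(
            {
                "center_um": d.center,
                "width_um": d.width,
                "shape": d.shape,
                "nominal_depth_um": d.depth,
                "surface_depth_um": m.depth,
                "floor_y_um": tr.start[1] + m.floor[0],
                "min_amplitude_um": amp,
            }
        )
    return out


def reference_perikymata_depths(
    spec: SyntheticSurfaceSpec,
    y0: float,
    y1: float,
    step: float | None = None,
    min_amplitude: float = DEFAULT_PERIKYMATA_AMPLITUDE,
) -> pd.DataFrame:
    """Convention perikymata depths on the dense noise-free surface in [y0, y1]."""
    step = step or spec.pixel_pitch / 4.0
    prof = _dense_profile(spec, y0, y1, step)
    ms = measure_perikymata_depths(prof, n_target=None, min_amplitude=min_amplitude)
    return pd.DataFrame(
        {
            "floor_y_um": [y0 + m.floor[0] for m in ms],
            "surface_depth_um": [m.depth for m in ms],
        }
    )


def nominal_groove_table(spec: SyntheticSurfaceSpec) -> pd.DataFrame:
    """Groove floor positions and nominal (feature-only) depths."""
    pk = spec.perikymata
    L = spec.extent[1]
    depths = _groove_depths(spec, _n_grooves(spec))
    t_floor = 0.5 ** (1.0 / (1.0 + pk.asymmetry))
    g = pk.spacing_gradient
    rows = []
    for k in range(len(depths)):
        phi = k + t_floor
        if g == 0:
            yk = phi * pk.mean_spacing
        else:
            yk = (L / g) * -np.expm1(-phi * pk.mean_spacing * g / L)
        if 0.0 <= yk <= L:
            rows.append({"groove_index": k, "floor_y_um": float(yk),
                         "nominal_depth_um": float(depths[k])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surface generation

@dataclass
class GroundTruth:
    """Known truth for one generated surface."""

    spec: SyntheticSurfaceSpec
    defects: list[dict]
    grooves: pd.DataFrame  # nominal per-groove depths and floor positions
    seed: int = 0


def generate_surface(spec: SyntheticSurfaceSpec) -> tuple[PointCloud, DEM, GroundTruth]:
    """Sample the synthetic surface on a regular grid with noise and dropouts.

    Regenerating with the same spec (including its seed) reproduces the
    surface and truth bit for bit.
    """
    w, length = spec.extent
    pitch = spec.pixel_pitch
    nx = int(np.floor(w / pitch + 1e-9)) + 1
    ny = int(np.floor(length / pitch + 1e-9)) + 1
    x = np.arange(nx) * pitch
    y = np.arange(ny) * pitch
    clean = clean_elevation(spec, y)[:, None] * np.ones((1, nx))
    z = clean.copy()
    base = spec.seed % (2**31)
    if spec.noise_sd > 0:
        z += np.random.default_rng([base, 12]).normal(0.0, spec.noise_sd, z.shape)
    if spec.spike_rate > 0:
        rng = np.random.default_rng([base, 13])
        hit = rng.random(z.shape) < spec.spike_rate
        z[hit] += spec.spike_amplitude * rng.choice([-1.0, 1.0], size=int(hit.sum()))
    mask = np.ones(z.shape, dtype=bool)
    if spec.dropout_rate > 0:
        mask &= np.random.default_rng([base, 14]).random(z.shape) >= spec.dropout_rate
    zc = z.copy()
    zc[~mask] = np.nan
    X, Y = np.meshgrid(x, y)
    cloud = PointCloud(
        points=np.column_stack([X.ravel(), Y.ravel(), zc.ravel()]),
        source_id=f"synthetic(seed={spec.seed})",
        lateral_pitch=pitch,
        z_step=1.0,
        measured=mask.ravel(),
    )
    dem = DEM(
        grid=zc,
        pixel_pitch=pitch,
        origin=(0.0, 0.0),
        occlusal_axis="row-",
        mask=mask,
        provenance=[f"generate_surface(seed={spec.seed})"],
    )
    truth = GroundTruth(
        spec=spec,
        defects=reference_defect_depths(spec),
        grooves=nominal_groove_table(spec),
        seed=spec.seed,
    )
    return cloud, dem, truth


# ---------------------------------------------------------------------------
# Cohorts of measurement records

@dataclass
class GroupSpec:
    """One taxon/temporal group of a simulated cohort."""

    name: str
    taxon: str
    temporal_group: str = ""
    n_specimens: int = 9
    teeth_per_specimen: int = 2
    pk_depth_gm: float = 1.5  # geometric-mean incisor perikymata depth, µm
    canine_factor: float = 1.7  # canines have deeper increments than incisors
    severity_gm: float = 17.0  # defect depth / tooth pk median
    severity_sd_log: float = 0.35
    specimen_sd_log: float = 0.25
    tooth_sd_log: float = 0.15
    pk_sd_log: float = 0.20
    n_pk_per_tooth: int = 10
    defects_per_tooth: int = 2


@dataclass
class CohortSpec:
    """Hierarchical cohort: groups > specimens > teeth > features."""

    groups: list[GroupSpec]
    fallback_fraction: float = 12.0 / 71.0
    matched_fraction: float = 0.5
    min_severity: float | None = None
    tooth_types: tuple[str, ...] = ("LC", "LI1", "LI2", "UC", "UI1", "UI2")

    def __post_init__(self) -> None:
        if not self.groups:
            raise SpecError("cohort needs at least one group")
        if not 0.0 <= self.fallback_fraction < 1.0:
            raise SpecError("fallback_fraction must be in [0, 1)")
        for g in self.groups:
            if g.n_specimens < 1 or g.teeth_per_specimen < 1:
                raise SpecError(f"group {g.name!r} must have specimens and teeth")


_CANINES = ("LC", "UC")


def generate_cohort(
    cohort: CohortSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate defect and perikymata records with known hierarchical truth.

    Specimen effects are multiplicative (lognormal) and shared by all of a
    specimen's teeth; each tooth has a true perikymata median; defect depth
    is a severity draw times the tooth's true median.  A ``fallback_fraction``
    of teeth is flagged pk_preserved = False and contributes no perikymata
    records (their defects must use the species/tooth-type fallback); the
    flagging never empties a (taxon, tooth type) reference pool.

    Returns (defect records, perikymata records, truth).
    """
    rng = np.random.default_rng(seed % (2**31))
    teeth: list[dict] = []
    truth: dict = {"specimen_effects": {}, "tooth_pk_median": {}, "groups": {}}
    for g in cohort.groups:
        truth["groups"][g.name] = {"pk_depth_gm": g.pk_depth_gm, "severity_gm": g.severity_gm}
        for s in range(g.n_specimens):
            spec_id = f"{g.name}_S{s:02d}"
            eff = float(np.exp(rng.normal(0.0, g.specimen_sd_log)))
            truth["specimen_effects"][spec_id] = eff
            for t in range(g.teeth_per_specimen):
                tooth_type = cohort.tooth_types[
                    (s * g.teeth_per_specimen + t) % len(cohort.tooth_types)
                ]
                cls = g.canine_factor if tooth_type in _CANINES else 1.0
                pk_median = (
                    g.pk_depth_gm * cls * eff * float(np.exp(rng.normal(0.0, g.tooth_sd_log)))
                )
                tooth_id = f"{spec_id}_{tooth_type}"
                truth["tooth_pk_median"][tooth_id] = pk_median
                teeth.append(
                    {
                        "group": g,
                        "specimen_id": spec_id,
                        "tooth_id": tooth_id,
                        "tooth_type": tooth_type,
                        "pk_median": pk_median,
                    }
                )
    # flag unpreserved teeth without emptying any (taxon, tooth_type) pool
    n_fallback = int(round(cohort.fallback_fraction * len(teeth)))
    order = rng.permutation(len(teeth))
    preserved = np.ones(len(teeth), dtype=bool)
    pool_counts: dict[tuple[str, str], int] = {}
    for i in range(len(teeth)):
        key = (teeth[i]["group"].taxon, teeth[i]["tooth_type"])
        pool_counts[key] = pool_counts.get(key, 0) + 1
    flipped = 0
    for i in order:
        if flipped == n_fallback:
            break
        key = (teeth[i]["group"].taxon, teeth[i]["tooth_type"])
        if pool_counts[key] <= 1:
            continue
        preserved[i] = False
        pool_counts[key] -= 1
        flipped += 1

    pk_rows, defect_rows = [], []
    feature_counter = 0
    for i, tooth in enumerate(teeth):
        g: GroupSpec = tooth["group"]
        base = {
            "specimen_id": tooth["specimen_id"],
            "taxon": g.taxon,
            "site": g.name,
            "temporal_group": g.temporal_group,
            "tooth_type": tooth["tooth_type"],
            "tooth_class": "canine" if tooth["tooth_type"] in _CANINES else "incisor",
            "pk_preserved": bool(preserved[i]),
        }
        if preserved[i]:
            for j in range(g.n_pk_per_tooth):
                pk_rows.append(
                    {
                        **base,
                        "feature_kind": "perikyma",
                        "feature_id": f"{tooth['tooth_id']}_pk{j:02d}",
                        "depth_um": tooth["pk_median"]
                        * float(np.exp(rng.normal(0.0, g.pk_sd_log))),
                    }
                )
        matched_id = (
            f"{tooth['specimen_id']}_ep0"
            if rng.random() < cohort.matched_fraction
            else None
        )
        for j in range(g.defects_per_tooth):
            sev = g.severity_gm * float(np.exp(rng.normal(0.0, g.severity_sd_log)))
            if cohort.min_severity is not None:
                sev = max(sev, cohort.min_severity)
            defect_rows.append(
                {
                    **base,
                    "feature_kind": "defect",
                    "feature_id": f"d{feature_counter:04d}",
                    "matched_group_id": matched_id if j == 0 else None,
                    "depth_um": sev * tooth["pk_median"],
                    "true_severity": sev,
                }
            )
            feature_counter += 1
    return pd.DataFrame(defect_rows), pd.DataFrame(pk_rows), truth
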