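"""Plane and sphere form removal, and quantification of the bias it induces.

Form-removal "leveling" subtracts a fitted geometric form (a plane or a
sphere) from a topography to flatten large-scale crown curvature before
measuring features.  Because the fit is dragged into deep defects, leveling
systematically under-estimates defect depth while making shallow growth
increments (perikymata) appear deeper; :func:`leveling_bias` reports both
effects per feature and in summary.

The form is always fitted to the whole DEM field, mimicking whole-field
leveling as applied by profilometer software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dem import DEM
from .exceptions import DegenerateGeometryError, PairingError, ParameterError

__all__ = ["FormParams", "LevelingReport", "fit_form", "remove_form", "leveling_bias"]


@dataclass
class FormParams:
    """Fitted form: z = a + b·x + c·y (plane) or a sphere (center, radius)."""

    form_kind: Literal["plane", "sphere"]
    plane: tuple[float, float, float] | None = None  # (a, b, c)
    sphere: tuple[float, float, float, float] | None = None  # (cx, cy, cz, R)
    sphere_branch: int = 1  # +1: data on upper hemisphere, -1: lower
    fit_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.form_kind == "plane" and self.plane is None:
            raise ParameterError("plane parameters required")
        if self.form_kind == "sphere":
            if self.sphere is None:
                raise ParameterError("sphere parameters required")
            if not self.sphere[3] > 0:
                raise ParameterError("sphere radius must be > 0")
        if self.fit_rms < 0:
            raise ParameterError("fit_rms must be >= 0")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Evaluate the form surface z(x, y); NaN outside a sphere's footprint."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.form_kind == "plane":
            a, b, c = self.plane
            return a + b * x + c * y
        cx, cy, cz, r = self.sphere
        rad2 = r * r - (x - cx) ** 2 - (y - cy) ** 2
        with np.errstate(invalid="ignore"):
            root = np.sqrt(np.where(rad2 >= 0, rad2, np.nan))
        return cz + self.sphere_branch * root


def _cells(dem: DEM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X, Y = np.meshgrid(dem.x_coords, dem.y_coords)
    m = dem.mask
    return X[m], Y[m], dem.grid[m]


def fit_form(dem: DEM, form_kind: Literal["plane", "sphere"]) -> FormParams:
    """Least-squares fit of a plane or sphere to all measured cells.

    Plane: ordinary least squares.  Sphere: algebraic (linearized) fit for a
    deterministic starting point, refined by iterative geometric least squares
    on the radial residuals (parameter tolerance 1e-6 µm, at most 100
    iterations).  ``fit_rms`` is the root-mean-square residual of the fit.
    """
    x, y, z = _cells(dem)
    if form_kind == "plane":
        if len(z) < 3:
            raise DegenerateGeometryError("plane fit needs >= 3 measured cells")
        A = np.column_stack([np.ones_like(x), x, y])
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        resid = z - A @ coef
        return FormParams(
            form_kind="plane",
            plane=tuple(float(c) for c in coef),
            fit_rms=float(np.sqrt(np.mean(resid**2))),
        )
    if form_kind != "sphere":
        raise ParameterError(f"unknown form kind {form_kind!r}")
    if len(z) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 measured cells")
    # algebraic (Kåsa) initialization: x²+y²+z² = 2cx·x + 2cy·y + 2cz·z + t
    A = np.column_stack([2 * x, 2 * y, 2 * z, np.ones_like(x)])
    b = x * x + y * y + z * z
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("sphere fit degenerate (coplanar cells?)")
    cx, cy, cz, t = sol
    r2 = t + cx * cx + cy * cy + cz * cz
    if not r2 > 0:
        raise DegenerateGeometryError("algebraic sphere fit produced radius <= 0")
    r0 = float(np.sqrt(r2))

    def radial(p: np.ndarray) -> np.ndarray:
        d = np.sqrt((x - p[0]) ** 2 + (y - p[1]) ** 2 + (z - p[2]) ** 2)
        return d - p[3]

    res = least_squares(
        radial,
        x0=np.array([cx, cy, cz, r0]),
        method="lm",
        xtol=1e-10,
        ftol=1e-12,
        max_nfev=100 * 5,
    )
    cx, cy, cz, r = res.x
    if not r > 0:
        raise DegenerateGeometryError("geometric sphere fit produced radius <= 0")
    branch = 1 if np.median(z) >= cz else -1
    return FormParams(
        form_kind="sphere",
        sphere=(float(cx), float(cy), float(cz), float(r)),
        sphere_branch=branch,
        fit_rms=float(np.sqrt(np.mean(res.fun**2))),
    )


def remove_form(dem: DEM, form: FormParams) -> DEM:
    """Subtract the fitted form: each measured cell becomes z − form(x, y).

    Unmeasured cells stay unmeasured; cells outside a sphere's footprint
    (no real form height) also become unmeasured.
    """
    X, Y = np.meshgrid(dem.x_coords, dem.y_coords)
    surf = form(X, Y)
    out = dem.grid - surf
    mask = dem.mask & np.isfinite(surf)
    out[~mask] = np.nan
    return DEM(
        grid=out,
        pixel_pitch=dem.pixel_pitch,
        origin=dem.origin,
        occlusal_axis=dem.occlusal_axis,
        mask=mask,
        provenance=dem.provenance + [f"remove_form({form.form_kind})"],
    )


@dataclass
class LevelingReport:
    """Per-feature raw-vs-leveled comparison with per-kind summaries.

    Sign conventions: for defects ``percent_difference`` is how much
    shallower the leveled value is (100·(raw − leveled)/raw, positive when
    leveling under-estimates); for perikymata it is how much deeper the
    leveled value appears (100·(leveled − raw)/raw).
    ``absolute_difference`` is |raw − leveled| in µm.
    """

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary, indent=2))


def leveling_bias(
    raw_measurements: pd.DataFrame, leveled_measurements: pd.DataFrame
) -> LevelingReport:
    """Pair raw and leveled depths by feature_id and quantify the bias.

    Both inputs need columns feature_id, feature_kind and depth_um, with the
    same feature_ids present in each.
    """
    cols = ["feature_id", "feature_kind", "depth_um"]
    for name, df in (("raw", raw_measurements), ("leveled", leveled_measurements)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise PairingError(f"{name} measurements missing columns {missing}")
    raw = raw_measurements[cols].rename(columns={"depth_um": "raw_depth_um"})
    lev = leveled_measurements[["feature_id", "depth_um"]].rename(
        columns={"depth_um": "leveled_depth_um"}
    )
    if set(raw["feature_id"]) != set(lev["feature_id"]):
        only_raw = set(raw["feature_id"]) - set(lev["feature_id"])
        only_lev = set(lev["feature_id"]) - set(raw["feature_id"])
        raise PairingError(
            f"unmatched feature_ids (raw-only {sorted(only_raw)}, "
            f"leveled-only {sorted(only_lev)})"
        )
    m = raw.merge(lev, on="feature_id", validate="one_to_one")
    signed = np.where(
        m["feature_kind"] == "defect",
        m["raw_depth_um"] - m["leveled_depth_um"],
        m["leveled_depth_um"] - m["raw_depth_um"],
    )
    m["percent_difference"] = 100.0 * signed / m["raw_depth_um"]
    m["absolute_difference_um"] = np.abs(m["raw_depth_um"] - m["leveled_depth_um"])
    summary = {}
    for kind, sub in m.groupby("feature_kind"):
        summary[kind] = {
            "n": int(len(sub)),
            "mean_percent_difference": float(sub["percent_difference"].mean()),
            "range_percent_difference": [
                float(sub["percent_difference"].min()),
                float(sub["percent_difference"].max()),
            ],
            "mean_absolute_difference_um": float(sub["absolute_difference_um"].mean()),
            "range_absolute_difference_um": [
                float(sub["absolute_difference_um"].min()),
                float(sub["absolute_difference_um"].max()),
            ],
        }
    return LevelingReport(table=m, summary=summary)
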