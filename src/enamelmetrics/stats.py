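"""LEH severity ratios, group summaries and the comparison statistics.

The central quantity is the LEH severity ratio: a defect's depth divided by
the median perikymata depth of the same tooth, which normalizes stress
severity for tooth- and species-specific enamel growth differences.  Where a
tooth's perikymata are too poorly preserved to measure, the median perikymata
depth of the same species and tooth type is used instead (the fallback rule).

Group comparisons use linear mixed models with a specimen-level random
intercept, because multiple defects and perikymata are measured per specimen
and matched defects across teeth of one dentition share a systemic stress
episode.  Depths are natural-log-transformed (their distributions are
right-skewed); severity ratios are log-transformed by default as well, which
preserves ratio symmetry.  Denominator degrees of freedom follow the
containment rule: number of specimens minus the number of fixed-effect
coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .exceptions import (
    DegenerateGeometryError,
    MissingReferenceError,
    ModelError,
    PairingError,
    ParameterError,
)

__all__ = [
    "StatsResult",
    "severity_ratios",
    "group_summary",
    "correlate_depths",
    "fit_group_model",
    "posthoc_contrasts",
    "replicability_compare",
]


@dataclass
class StatsResult:
    """Container for one analysis: estimates, test statistics, p-values."""

    analysis_kind: Literal["correlation", "mixed_model", "posthoc", "paired"]
    estimates: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    transformation: str = "none"
    formula: str = ""
    table: pd.DataFrame | None = None
    model_result: object | None = None  # fitted statsmodels result, for posthoc

    def to_dict(self) -> dict:
        return {
            "analysis_kind": self.analysis_kind,
            "estimates": self.estimates,
            "statistics": self.statistics,
            "p_values": self.p_values,
            "transformation": self.transformation,
            "formula": self.formula,
        }


# ---------------------------------------------------------------------------
# Severity ratios

def severity_ratios(defects: pd.DataFrame, perikymata: pd.DataFrame) -> pd.DataFrame:
    """Per-defect severity ratio with the same-tooth / species fallback rule.

    ``defects`` needs columns specimen_id, taxon, tooth_type, feature_id,
    depth_um and pk_preserved; ``perikymata`` needs specimen_id, taxon,
    tooth_type, depth_um.  Returns one row per defect with the reference
    depth, the reference kind used, and the ratio.
    """
    need_d = ["specimen_id", "taxon", "tooth_type", "feature_id", "depth_um", "pk_preserved"]
    need_p = ["specimen_id", "taxon", "tooth_type", "depth_um"]
    for name, df, need in (("defects", defects, need_d), ("perikymata", perikymata, need_p)):
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ParameterError(f"{name} table missing columns {missing}")
    rows = []
    for _, d in defects.iterrows():
        same_tooth = perikymata[
            (perikymata["specimen_id"] == d["specimen_id"])
            & (perikymata["tooth_type"] == d["tooth_type"])
        ]["depth_um"]
        pool = perikymata[
            (perikymata["taxon"] == d["taxon"])
            & (perikymata["tooth_type"] == d["tooth_type"])
        ]["depth_um"]
        if bool(d["pk_preserved"]) and len(same_tooth) > 0:
            ref_kind = "same_tooth_median"
            ref = float(same_tooth.median())
        elif len(pool) > 0:
            ref_kind = "species_toothtype_median"
            ref = float(pool.median())
        else:
            raise MissingReferenceError(
                f"defect {d['feature_id']!r}: no perikymata reference at either level"
            )
        if not ref > 0:
            raise MissingReferenceError(
                f"defect {d['feature_id']!r}: nonpositive reference depth {ref}"
            )
        rows.append(
            {
                "feature_id": d["feature_id"],
                "specimen_id": d["specimen_id"],
                "taxon": d["taxon"],
                "tooth_type": d["tooth_type"],
                "defect_depth_um": float(d["depth_um"]),
                "reference_kind": ref_kind,
                "reference_depth_um": ref,
                "ratio": float(d["depth_um"]) / ref,
            }
        )
    return pd.DataFrame(rows)


def group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """n, median, min and max depth per (taxon, tooth_type, feature_kind)."""
    if records.empty:
        raise ParameterError("no records to summarize")
    g = records.groupby(["taxon", "tooth_type", "feature_kind"], dropna=False)["depth_um"]
    out = g.agg(n="count", median_um="median", min_um="min", max_um="max").reset_index()
    return out


# ---------------------------------------------------------------------------
# Correlation

def correlate_depths(
    pk_medians: Sequence[float], defect_medians: Sequence[float]
) -> StatsResult:
    """Pearson correlation of natural-log tooth medians (pk vs defect depth)."""
    x = np.asarray(pk_medians, dtype=float)
    y = np.asarray(defect_medians, dtype=float)
    if len(x) != len(y):
        raise ParameterError("pk and defect median vectors must be the same length")
    if len(x) < 3:
        raise ParameterError("need at least 3 teeth with both medians")
    if (x <= 0).any() or (y <= 0).any():
        raise ParameterError("depths must be positive for the log transform")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        raise DegenerateGeometryError("zero variance in one of the variables")
    r, p = sps.pearsonr(lx, ly)
    return StatsResult(
        analysis_kind="correlation",
        estimates={"r": float(r), "r_squared": float(r * r)},
        statistics={"n": int(len(x))},
        p_values={"two_sided": float(p)},
        transformation="natural_log",
        formula="pearson(log pk tooth median, log defect tooth median)",
    )


# ---------------------------------------------------------------------------
# Mixed models

def _wald_f(result, term_idx: np.ndarray, den_df: int) -> tuple[float, int, int, float]:
    beta = np.asarray(result.fe_params)[term_idx]
    cov = np.asarray(result.cov_params())[np.ix_(term_idx, term_idx)]
    q = len(term_idx)
    if np.allclose(beta, 0.0, atol=1e-10):
        # degenerate case (e.g. all responses identical): no effect, F = 0
        return 0.0, q, den_df, 1.0
    try:
        f = float(beta @ np.linalg.solve(cov, beta) / q)
    except np.linalg.LinAlgError:
        f = float(beta @ np.linalg.pinv(cov) @ beta / q)
    p = float(sps.f.sf(f, q, den_df))
    return f, q, den_df, p


def fit_group_model(
    records: pd.DataFrame,
    response: str = "depth_um",
    fixed_factor: str = "taxon",
    random_intercept: str = "specimen_id",
    log_response: bool = True,
) -> StatsResult:
    """Linear mixed model with a specimen random intercept, REML-fitted.

    Reports the Wald F test of the fixed factor with containment denominator
    degrees of freedom (n specimens − n fixed coefficients), which reproduces
    the dfs conventional mixed-model software prints for between-specimen
    factors.
    """
    for col in (response, fixed_factor, random_intercept):
        if col not in records.columns:
            raise ParameterError(f"records missing column {col!r}")
    df = records[[response, fixed_factor, random_intercept]].dropna().copy()
    levels = df[fixed_factor].unique()
    if len(levels) < 2:
        raise ModelError(f"fixed factor {fixed_factor!r} needs >= 2 levels")
    n_spec = df[random_intercept].nunique()
    if n_spec < 2:
        raise ModelError(
            "only one specimen: the random intercept is inestimable; "
            "fit a fixed-effects model instead"
        )
    y = df[response].to_numpy(dtype=float)
    if log_response:
        if (y <= 0).any():
            raise ParameterError("responses must be positive for the log transform")
        df["_y"] = np.log(y)
        transform = "natural_log"
    else:
        df["_y"] = y
        transform = "none"
    formula = f"_y ~ C({fixed_factor})"
    model = smf.mixedlm(formula, df, groups=df[random_intercept])
    with warnings.catch_warnings():
        # boundary REML fits (zero specimen variance) are routine, not errors
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message="Random effects covariance is singular")
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            result = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # gradient-based optimizers can hit singular profiled covariances
            result = model.fit(reml=True, method="powell")
    names = list(result.fe_params.index)
    term_idx = np.array(
        [i for i, n in enumerate(names) if n.startswith(f"C({fixed_factor})")]
    )
    den_df = n_spec - len(names)
    if den_df < 1:
        raise ModelError("not enough specimens for the containment denominator df")
    f, q, den, p = _wald_f(result, term_idx, den_df)
    return StatsResult(
        analysis_kind="mixed_model",
        estimates={
            "fixed_effects": {n: float(v) for n, v in result.fe_params.items()},
            "random_intercept_var": float(np.asarray(result.cov_re).ravel()[0]),
            "residual_var": float(result.scale),
        },
        statistics={"F": f, "df_num": q, "df_den": den, "n_specimens": int(n_spec)},
        p_values={"fixed_factor": p},
        transformation=transform,
        formula=(f"log({response})" if log_response else response)
        + f" ~ {fixed_factor} + (1 | {random_intercept})",
        model_result=result,
    )


def fixed_effect_ci(model: StatsResult, term: str, alpha: float = 0.05) -> tuple[float, float]:
    """Containment-df t interval for one fixed-effect coefficient."""
    result = model.model_result
    if result is None:
        raise ModelError("StatsResult carries no fitted model")
    names = list(result.fe_params.index)
    if term not in names:
        raise ParameterError(f"unknown term {term!r}; have {names}")
    i = names.index(term)
    est = float(result.fe_params.iloc[i])
    se = float(np.sqrt(np.asarray(result.cov_params())[i, i]))
    den_df = model.statistics["df_den"]
    tcrit = sps.t.ppf(1 - alpha / 2, den_df)
    return est - tcrit * se, est + tcrit * se


def posthoc_contrasts(
    model: StatsResult, factor: str, method: Literal["tukey", "holm"] = "tukey"
) -> StatsResult:
    """All pairwise contrasts of the factor levels with adjusted p-values.

    Tukey-style adjustment uses the studentized-range distribution on the
    containment denominator df; Holm adjusts the per-contrast t p-values.
    """
    result = model.model_result
    if result is None:
        raise ModelError("StatsResult carries no fitted model")
    names = list(result.fe_params.index)
    prefix = f"C({factor})[T."
    level_terms = {n[len(prefix):-1]: i for i, n in enumerate(names) if n.startswith(prefix)}
    if not level_terms:
        raise ParameterError(f"factor {factor!r} not found in the fitted model")
    # reference level: the category without its own coefficient
    ref = "<reference>"
    try:
        di = result.model.data.design_info
        for fac, info in di.factor_infos.items():
            if factor in fac.name() and info.categories is not None:
                cats = [str(c) for c in info.categories]
                ref = next(c for c in cats if c not in level_terms)
                break
    except (AttributeError, StopIteration):
        pass
    levels = [ref] + sorted(level_terms)
    k = len(levels)
    if k == 2:
        warnings.warn(
            "2-level factor: the pairwise contrast equals the main test",
            stacklevel=2,
        )
    cov = np.asarray(result.cov_params())[: len(names), : len(names)]
    beta = np.asarray(result.fe_params)
    den_df = model.statistics["df_den"]

    def coef_vec(level: str) -> np.ndarray:
        v = np.zeros(len(names))
        if level != ref:
            v[level_terms[level]] = 1.0
        return v

    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            la, lb = levels[a], levels[b]
            cvec = coef_vec(lb) - coef_vec(la)
            diff = float(cvec @ beta)
            se = float(np.sqrt(cvec @ cov @ cvec))
            t = diff / se
            p_unadj = float(2 * sps.t.sf(abs(t), den_df))
            rows.append({"level_a": la, "level_b": lb, "estimate": diff, "se": se,
                         "t": t, "p_unadjusted": p_unadj})
    tab = pd.DataFrame(rows)
    if method == "tukey":
        tab["p_adjusted"] = [
            float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, den_df))
            for t in tab["t"]
        ]
    elif method == "holm":
        tab["p_adjusted"] = multipletests(tab["p_unadjusted"], method="holm")[1]
    else:
        raise ParameterError(f"unknown adjustment method {method!r}")
    tab["p_adjusted"] = np.maximum(tab["p_adjusted"], tab["p_unadjusted"])
    return StatsResult(
        analysis_kind="posthoc",
        estimates={"adjustment": method, "n_contrasts": int(len(tab))},
        statistics={"df_den": den_df, "k_levels": k},
        p_values={f"{r.level_a} vs {r.level_b}": float(r.p_adjusted) for r in tab.itertuples()},
        transformation=model.transformation,
        formula=model.formula + f" ; all pairwise {factor} contrasts ({method})",
        table=tab,
    )


# ---------------------------------------------------------------------------
# Replicability

def replicability_compare(
    session_a: pd.DataFrame, session_b: pd.DataFrame
) -> StatsResult:
    """Paired comparison of matched depths from two imaging sessions.

    Percent differences use the symmetric denominator (the pair mean), so
    neither session is privileged.  Inputs need feature_id, feature_kind and
    depth_um with matching feature_ids.
    """
    cols = ["feature_id", "feature_kind", "depth_um"]
    for name, df in (("session_a", session_a), ("session_b", session_b)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise PairingError(f"{name} missing columns {missing}")
    if set(session_a["feature_id"]) != set(session_b["feature_id"]):
        raise PairingError("sessions do not share the same feature_ids")
    a = session_a[cols].rename(columns={"depth_um": "depth_a"})
    b = session_b[["feature_id", "depth_um"]].rename(columns={"depth_um": "depth_b"})
    m = a.merge(b, on="feature_id", validate="one_to_one")
    m["absolute_difference_um"] = (m["depth_a"] - m["depth_b"]).abs()
    m["percent_difference"] = (
        100.0 * m["absolute_difference_um"] / ((m["depth_a"] + m["depth_b"]) / 2.0)
    )
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
    return StatsResult(
        analysis_kind="paired",
        estimates=summary,
        statistics={"n_pairs": int(len(m))},
        p_values={},
        transformation="none",
        formula="paired percent difference, symmetric (pair-mean) denominator",
        table=m,
    )
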