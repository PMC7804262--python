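"""Severity ratios, group summaries, correlation, mixed models, replicability."""

import numpy as np
import pandas as pd
import pytest

from enamelmetrics.exceptions import (
    MissingReferenceError,
    ModelError,
    PairingError,
    ParameterError,
)
from enamelmetrics.reference_data import published_depth_table
from enamelmetrics.stats import (
    correlate_depths,
    fit_group_model,
    fixed_effect_ci,
    group_summary,
    posthoc_contrasts,
    replicability_compare,
    severity_ratios,
)
from enamelmetrics.synthetic import CohortSpec, GroupSpec, generate_cohort


def _defect(feature_id, depth, specimen="S1", tooth="LC", taxon="Neanderthal", preserved=True):
    return {
        "specimen_id": specimen,
        "taxon": taxon,
        "tooth_type": tooth,
        "feature_id": feature_id,
        "depth_um": depth,
        "pk_preserved": preserved,
    }


def _pk(depth, specimen="S1", tooth="LC", taxon="Neanderthal"):
    return {
        "specimen_id": specimen,
        "taxon": taxon,
        "tooth_type": tooth,
        "depth_um": depth,
    }


class TestSeverityRatios:
    def test_published_median_worked_example(self):
        # defect 26.4 µm against a tooth whose pk median is 1.57 µm -> 16.8
        defects = pd.DataFrame([_defect("d1", 26.4)])
        pk = pd.DataFrame([_pk(1.57), _pk(1.40), _pk(1.74)])
        out = severity_ratios(defects, pk)
        assert round(out["ratio"].iloc[0], 1) == 16.8
        assert out["reference_kind"].iloc[0] == "same_tooth_median"

    def test_simple_ratio(self):
        out = severity_ratios(
            pd.DataFrame([_defect("d1", 10.0)]), pd.DataFrame([_pk(1.0)])
        )
        assert out["ratio"].iloc[0] == pytest.approx(10.0)

    def test_fallback_uses_species_toothtype_pool(self):
        defects = pd.DataFrame([_defect("d1", 20.0, specimen="S9", preserved=False)])
        pool = [  # perikymata from other specimens of the same species+tooth
            _pk(d, specimen=s) for s, d in [("S1", 1.0), ("S2", 2.0), ("S3", 4.0)]
        ]
        out = severity_ratios(defects, pd.DataFrame(pool))
        assert out["reference_kind"].iloc[0] == "species_toothtype_median"
        assert out["reference_depth_um"].iloc[0] == pytest.approx(np.median([1, 2, 4]))

    def test_missing_reference_error_names_defect(self):
        defects = pd.DataFrame([_defect("d7", 20.0, tooth="UI2")])
        pk = pd.DataFrame([_pk(1.0, tooth="LC")])
        with pytest.raises(MissingReferenceError, match="d7"):
            severity_ratios(defects, pk)

    def test_ratio_invariant_under_unit_rescale(self):
        defects = pd.DataFrame([_defect("d1", 26.4)])
        pk = pd.DataFrame([_pk(1.57), _pk(1.40), _pk(1.74)])
        a = severity_ratios(defects, pk)["ratio"].iloc[0]
        defects2 = defects.assign(depth_um=defects["depth_um"] * 1000)
        pk2 = pk.assign(depth_um=pk["depth_um"] * 1000)
        b = severity_ratios(defects2, pk2)["ratio"].iloc[0]
        assert a == pytest.approx(b)

    def test_fallback_count_matches_flags_on_cohort(self):
        cohort = CohortSpec(
            groups=[
                GroupSpec(name="nea", taxon="Neanderthal", n_specimens=9),
                GroupSpec(name="sap", taxon="H. sapiens", n_specimens=9),
            ],
            fallback_fraction=12.0 / 71.0,
        )
        defects, pk, _ = generate_cohort(cohort, seed=3)
        ratios = severity_ratios(defects, pk)
        merged = ratios.merge(defects[["feature_id", "pk_preserved"]], on="feature_id")
        fall = merged["reference_kind"] == "species_toothtype_median"
        assert (fall == ~merged["pk_preserved"]).all()


class TestGroupSummary:
    def test_median_and_range(self):
        df = pd.DataFrame(
            [
                {"taxon": "N", "tooth_type": "LC", "feature_kind": "perikyma", "depth_um": d}
                for d in (1.0, 2.0, 3.0)
            ]
        )
        out = group_summary(df)
        assert out.loc[0, ["n", "median_um", "min_um", "max_um"]].tolist() == [3, 2.0, 1.0, 3.0]

    def test_even_group_median_is_midpoint(self):
        df = pd.DataFrame(
            [
                {"taxon": "N", "tooth_type": "LC", "feature_kind": "defect", "depth_um": d}
                for d in (10.0, 20.0, 30.0, 50.0)
            ]
        )
        assert group_summary(df)["median_um"].iloc[0] == pytest.approx(25.0)

    def test_matches_brute_force_order_statistics(self):
        rng = np.random.default_rng(0)
        rows = []
        for taxon in ("A", "B"):
            for tt in ("LC", "UI1"):
                for d in rng.lognormal(1.0, 0.5, size=rng.integers(3, 12)):
                    rows.append({"taxon": taxon, "tooth_type": tt,
                                 "feature_kind": "perikyma", "depth_um": d})
        df = pd.DataFrame(rows)
        out = group_summary(df).set_index(["taxon", "tooth_type"])
        for (taxon, tt), sub in df.groupby(["taxon", "tooth_type"]):
            v = np.sort(sub["depth_um"].to_numpy())
            n = len(v)
            med = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
            row = out.loc[(taxon, tt)]
            assert row["median_um"] == pytest.approx(med)
            assert row["min_um"] == pytest.approx(v[0])
            assert row["max_um"] == pytest.approx(v[-1])

    def test_published_table_row_structure(self):
        tab = published_depth_table()
        assert list(tab["tooth_type"].unique()) == ["LC", "LI1", "LI2", "UC", "UI1", "UI2"]
        nea = tab[tab["taxon"] == "Neanderthal"].set_index("tooth_type")
        assert nea.loc["LC", "n_perikymata"] == 10


class TestCorrelateDepths:
    def test_proportional_pairs_r2_one(self):
        pk = np.array([1.0, 1.5, 2.5, 4.0])
        res = correlate_depths(pk, 17.0 * pk)
        assert res.estimates["r_squared"] == pytest.approx(1.0)

    def test_null_r2_near_expectation(self):
        # independent pairs: E[R^2] = 1/(n-1); p approximately uniform
        rng = np.random.default_rng(1)
        n, reps = 29, 400
        r2s, ps = [], []
        for _ in range(reps):
            res = correlate_depths(rng.lognormal(0, 0.4, n), rng.lognormal(3, 0.4, n))
            r2s.append(res.estimates["r_squared"])
            ps.append(res.p_values["two_sided"])
        assert np.mean(r2s) == pytest.approx(1.0 / (n - 1), abs=0.015)
        assert 0.35 <= np.mean(ps) <= 0.65

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ParameterError, match="positive"):
            correlate_depths([1.0, 0.0, 2.0], [3.0, 4.0, 5.0])

    def test_too_few_teeth_rejected(self):
        with pytest.raises(ParameterError):
            correlate_depths([1.0, 2.0], [3.0, 4.0])


def _two_group_records(rng, effect=1.0, n_spec=18, teeth=3, spec_sd=0.25, noise_sd=0.2):
    rows = []
    for s in range(n_spec):
        g = "A" if s < n_spec // 2 else "B"
        e = rng.normal(0.0, spec_sd)
        for _ in range(teeth):
            depth = 1.5 * (effect if g == "B" else 1.0) * np.exp(e + rng.normal(0, noise_sd))
            rows.append({"specimen_id": f"S{s}", "taxon": g, "depth_um": depth})
    return pd.DataFrame(rows)


class TestFitGroupModel:
    def test_containment_denominator_df(self):
        rng = np.random.default_rng(2)
        res = fit_group_model(_two_group_records(rng), fixed_factor="taxon")
        assert res.statistics["df_num"] == 1
        assert res.statistics["df_den"] == 16  # 18 specimens - 2 coefficients

    def test_identical_groups_small_f(self):
        rows = []
        for s in range(8):
            for _ in range(3):
                rows.append({"specimen_id": f"S{s}", "taxon": "A" if s < 4 else "B",
                             "depth_um": 2.0})
        res = fit_group_model(pd.DataFrame(rows), fixed_factor="taxon")
        assert res.statistics["F"] == pytest.approx(0.0, abs=1e-6)

    def test_single_specimen_rejected(self):
        df = pd.DataFrame(
            {"specimen_id": ["S1"] * 6, "taxon": list("AAABBB"), "depth_um": [1.0] * 6}
        )
        with pytest.raises(ModelError, match="fixed-effects"):
            fit_group_model(df, fixed_factor="taxon")

    def test_effect_recovered_on_log_scale(self):
        rng = np.random.default_rng(3)
        res = fit_group_model(_two_group_records(rng, effect=2.33, n_spec=30),
                              fixed_factor="taxon")
        term = next(k for k in res.estimates["fixed_effects"] if k.startswith("C("))
        lo, hi = fixed_effect_ci(res, term)
        assert lo < np.log(2.33) < hi


class TestPosthocContrasts:
    def _four_group_model(self, rng, shift=0.0):
        rows = []
        for s in range(20):
            g = ["MP", "UP", "Neolithic", "Medieval"][s % 4]
            e = rng.normal(0, 0.2)
            mult = np.exp(shift) if g == "Neolithic" else 1.0
            for _ in range(3):
                rows.append({"specimen_id": f"S{s}", "temporal_group": g,
                             "depth_um": 17.0 * mult * np.exp(e + rng.normal(0, 0.2))})
        return fit_group_model(pd.DataFrame(rows), fixed_factor="temporal_group")

    def test_null_groups_large_adjusted_p(self):
        model = self._four_group_model(np.random.default_rng(4))
        ph = posthoc_contrasts(model, "temporal_group")
        assert min(ph.p_values.values()) > 0.01  # no spurious strong signal

    def test_one_shifted_group_flagged(self):
        model = self._four_group_model(np.random.default_rng(5), shift=-1.0)
        ph = posthoc_contrasts(model, "temporal_group")
        hits = {k: p for k, p in ph.p_values.items() if p < 0.05}
        assert len(hits) == 3
        assert all("Neolithic" in k for k in hits)

    def test_adjusted_never_below_unadjusted(self):
        model = self._four_group_model(np.random.default_rng(6), shift=-0.5)
        for method in ("tukey", "holm"):
            ph = posthoc_contrasts(model, "temporal_group", method=method)
            assert (ph.table["p_adjusted"] >= ph.table["p_unadjusted"] - 1e-12).all()

    def test_two_level_factor_warns_redundant(self):
        rng = np.random.default_rng(7)
        model = fit_group_model(_two_group_records(rng), fixed_factor="taxon")
        with pytest.warns(UserWarning, match="equals the main test"):
            posthoc_contrasts(model, "taxon")


class TestReplicabilityCompare:
    def test_identical_sessions_zero(self):
        df = pd.DataFrame(
            {"feature_id": ["a", "b"], "feature_kind": ["defect", "perikyma"],
             "depth_um": [30.0, 1.5]}
        )
        res = replicability_compare(df, df.copy())
        assert np.allclose(res.table["percent_difference"], 0.0)

    def test_symmetric_denominator_percent(self):
        a = pd.DataFrame({"feature_id": ["d1"], "feature_kind": ["defect"], "depth_um": [30.0]})
        b = pd.DataFrame({"feature_id": ["d1"], "feature_kind": ["defect"], "depth_um": [30.69]})
        res = replicability_compare(a, b)
        assert round(res.table["percent_difference"].iloc[0], 1) == 2.3

    def test_report_mean_is_hand_computed(self):
        rng = np.random.default_rng(8)
        da = rng.uniform(10, 50, 5)
        db = da * rng.uniform(0.95, 1.05, 5)
        a = pd.DataFrame({"feature_id": [f"d{i}" for i in range(5)],
                          "feature_kind": ["defect"] * 5, "depth_um": da})
        b = a.assign(depth_um=db)
        res = replicability_compare(a, b)
        expect = np.mean(100 * np.abs(da - db) / ((da + db) / 2))
        assert res.estimates["defect"]["mean_percent_difference"] == pytest.approx(expect)

    def test_unmatched_ids_error(self):
        a = pd.DataFrame({"feature_id": ["x"], "feature_kind": ["defect"], "depth_um": [1.0]})
        b = pd.DataFrame({"feature_id": ["y"], "feature_kind": ["defect"], "depth_um": [1.0]})
        with pytest.raises(PairingError):
            replicability_compare(a, b)
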