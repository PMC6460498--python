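"""Missingness regressions: design construction, fitting, recovery, VIF."""

import numpy as np
import pandas as pd
import pytest

from medconcord import (build_patient_design, build_record_design,
                        classify_patients, fit_clustered_logit,
                        fit_patient_fn_model, vif_diagnostic)
from medconcord.models import assign_age_band

from _oracles import simulate_logit_design
from conftest import patient_frame, prepared_frame


class TestRecordDesign:
    def _design(self):
        dp = prepared_frame([(f"d{i}", "A", i * 40, "55555-0002-01")
                             for i in range(10)], stream="dispensing")
        flags = pd.Series([True] * 7 + [False] * 3, index=dp["record_id"])
        return build_record_design(dp, flags, patient_frame(["A"]))

    def test_one_row_per_record_with_flag_complement(self):
        design = self._design()
        assert len(design) == 10
        assert int(design["outcome"].sum()) == 3

    def test_all_matched_means_all_outcomes_false(self):
        dp = prepared_frame([("d1", "A", 0, "55555-0002-01")], stream="dispensing")
        flags = pd.Series([True], index=dp["record_id"])
        design = build_record_design(dp, flags, patient_frame(["A"]))
        assert not design["outcome"].any()

    def test_missing_tier_kept_as_explicit_level(self):
        dp = prepared_frame([("d1", "A", 0, "55555-0002-01")], stream="dispensing")
        dp["tier"] = "other_missing"
        design = build_record_design(dp, pd.Series([False], index=dp["record_id"]),
                                     patient_frame(["A"]))
        assert design.loc[0, "tier"] == "other_missing"

    def test_age_bands(self):
        assert assign_age_band([0]).iloc[0] == "0-<6"
        assert assign_age_band([200]).iloc[0] == "6-<12"
        assert assign_age_band([800]).iloc[0] == "24-<60"
        assert assign_age_band([4000]).iloc[0] == "60-<=132"


class TestPatientDesign:
    def _patients(self, n=40):
        pats = patient_frame([f"P{i}" for i in range(n)])
        pats["encounter_count"] = np.arange(1, n + 1)
        return pats

    def test_outcome_is_false_negative(self):
        pats = self._patients(4)
        cls = pd.DataFrame({"patid": pats["patid"],
                            "cell": ["TP", "TN", "FN", "FP"]})
        design = build_patient_design(cls, pats)
        assert design["outcome"].tolist() == [False, False, True, False]

    def test_data_quartiles_are_balanced(self):
        pats = self._patients(40)
        cls = pd.DataFrame({"patid": pats["patid"], "cell": ["TP"] * 40})
        design = build_patient_design(cls, pats)
        assert design["enc_quartile"].value_counts().tolist() == [10, 10, 10, 10]

    def test_fixed_cuts(self):
        pats = self._patients(4)
        pats["encounter_count"] = [5, 25, 40, 100]
        cls = pd.DataFrame({"patid": pats["patid"], "cell": ["TP"] * 4})
        design = build_patient_design(cls, pats, quartile_mode="fixed")
        assert design["enc_quartile"].tolist() == ["Q1", "Q2", "Q3", "Q4"]


class TestFitClusteredLogit:
    def test_one_level_outcome_rejected(self):
        d = simulate_logit_design(0, n=200)
        d["outcome"] = False
        with pytest.raises(ValueError, match="one level"):
            fit_clustered_logit(d, covariates=[("xcov", "no")])

    def test_null_covariate_ci_covers_one(self):
        d = simulate_logit_design(1, n=20000, beta=0.0)
        fit = fit_clustered_logit(d, covariates=[("xcov", "no")])
        row = fit.term("xcov[yes]")
        assert row["ci_low"] <= 1.0 <= row["ci_high"]
        assert not row["significant"]

    def test_recovers_known_odds_ratio(self):
        d = simulate_logit_design(2, n=50000, beta=np.log(1.5))
        fit = fit_clustered_logit(d, covariates=[("xcov", "no")])
        row = fit.term("xcov[yes]")
        assert 1.35 <= row["or_"] <= 1.65
        assert row["ci_low"] <= 1.5 <= row["ci_high"]
        assert fit.converged and fit.method == "logit+cluster_robust"

    def test_single_cluster_falls_back_with_warning(self):
        d = simulate_logit_design(3, n=5000, beta=np.log(2.0), n_inst=1, re_sd=0)
        with pytest.warns(UserWarning, match="single cluster"):
            fit = fit_clustered_logit(d, covariates=[("xcov", "no")])
        assert fit.method == "logit"

    def test_gee_method_close_to_robust_logit(self):
        d = simulate_logit_design(4, n=8000, beta=np.log(1.5))
        a = fit_clustered_logit(d, covariates=[("xcov", "no")])
        b = fit_clustered_logit(d, covariates=[("xcov", "no")], method="gee")
        assert a.term("xcov[yes]")["or_"] == pytest.approx(
            b.term("xcov[yes]")["or_"], rel=0.02)

    def test_wald_ci_brackets_or(self):
        d = simulate_logit_design(5, n=5000, beta=np.log(1.5))
        t = fit_clustered_logit(d, covariates=[("xcov", "no")]).table
        assert ((t["ci_low"] <= t["or_"]) & (t["or_"] <= t["ci_high"])).all()
        assert (t["or_"] > 0).all()


class TestEndToEndRecovery:
    def test_asthma_effect_recovered_by_fn_model(self, lexicon):
        """Whole-patient capture-failure OR configured at 3.0 is recovered
        from the generated cohort by the patient-level false-negative model."""
        from medconcord import generate_cohort, load_profile, match_directional
        from medconcord.prepare import prepare_stream

        from dataclasses import replace

        cfg = load_profile("cids_default", seed=11, n_patients=30000)
        cfg = cfg.with_overrides(
            patient_effects={"asthma": np.log(3.0)},
            # make false negatives common enough to estimate precisely
            institutions=[replace(p, p_patient_rx_noncapture=0.05)
                          for p in cfg.institutions])
        tables, _ = generate_cohort(cfg, lexicon)
        enc, dx = tables.encounter, tables.diagnosis
        rx, _ = prepare_stream(tables.prescribing, enc, dx, lexicon)
        dp, _ = prepare_stream(tables.dispensing, enc, dx, lexicon)
        cls = classify_patients(rx, dp, tables.demographic)
        design = build_patient_design(cls, tables.demographic)
        fit = fit_patient_fn_model(design)
        row = fit.term("asthma[True]")
        assert 2.4 <= row["or_"] <= 3.6


class TestVif:
    def test_independent_covariates_near_one(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"a": rng.integers(0, 2, 2000).astype(bool),
                          "b": rng.integers(0, 2, 2000).astype(bool),
                          "outcome": rng.integers(0, 2, 2000).astype(bool)})
        vifs = vif_diagnostic(d, covariates=[("a", False), ("b", False)])
        assert (vifs < 1.1).all()

    def test_duplicated_column_is_infinite(self):
        d = pd.DataFrame({"a": [True, False] * 50})
        d["b"] = d["a"]
        d["outcome"] = [True, False] * 50
        vifs = vif_diagnostic(d, covariates=[("a", False), ("b", False)])
        assert np.isinf(vifs).all()

    def test_known_r_squared_gives_closed_form(self):
        # x2 = sqrt(3)*x1 + z with z orthogonal to x1 => R^2 = 0.75, VIF = 4
        x1 = np.array([1.0, 1.0, -1.0, -1.0] * 25)
        z = np.array([1.0, -1.0, 1.0, -1.0] * 25)
        d = pd.DataFrame({"x1": x1, "x2": np.sqrt(3) * x1 + z,
                          "outcome": x1 > 0})
        vifs = vif_diagnostic(d, covariates=[("x1", None), ("x2", None)])
        assert vifs["x1"] == pytest.approx(4.0, abs=1e-9)
        assert vifs["x2"] == pytest.approx(4.0, abs=1e-9)
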