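"""Post-selection refits and secondary analyses: oracle agreement, nested
likelihood orderings, sensitivity filters, and the univariate track."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_cohort, simulate_pairs
from pancanmet.clogit import fit_clogit, natural_spline_basis
from pancanmet.dslasso import OVERALL, DataSharedLasso, build_pair_differences
from pancanmet.postfit import (
    SensitivitySpec,
    bmi_effect_modification,
    extended_typespecific_comparison,
    refit_unpenalized,
    sensitivity_refit,
    spline_linearity_test,
    univariate_clogit,
)


class TestRefitUnpenalized:
    def test_empty_support_null_model(self):
        rng = np.random.default_rng(0)
        feats, cohort = simulate_pairs(rng, 25, [0.0])
        design = build_pair_differences(feats, cohort)
        res = refit_unpenalized([], design)
        assert res.empty
        assert res.loglik == pytest.approx(25 * np.log(0.5))

    def test_single_feature_matches_conditional_logit_oracle(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(1)
        feats, cohort = simulate_pairs(rng, 150, [0.4])
        design = build_pair_differences(feats, cohort)
        res = refit_unpenalized([("f0", OVERALL)], design)
        endog = np.r_[np.ones(150), np.zeros(150)]
        exog = np.r_[
            feats.loc[cohort.pairs["case_id"], "f0"].values,
            feats.loc[cohort.pairs["control_id"], "f0"].values,
        ][:, None]
        groups = np.r_[np.arange(150), np.arange(150)]
        oracle = ConditionalLogit(endog, exog, groups=groups).fit(
            method="newton", disp=False
        )
        row = res.table.loc[("f0", OVERALL)]
        assert row["estimate"] == pytest.approx(oracle.params[0], abs=1e-8)
        assert row["se"] == pytest.approx(oracle.bse[0], rel=1e-4)

    def test_separation_reported_not_raised(self):
        D = pd.DataFrame({"f0": np.ones(10)})  # perfectly separated differences
        from pancanmet.dslasso import PairDiffDesign

        design = PairDiffDesign(D=D, type_of_pair=pd.Series(["T1"] * 10, index=D.index))
        res = refit_unpenalized([("f0", OVERALL)], design)
        assert not res.table["estimable"].iloc[0]

    def test_estimate_near_truth(self):
        rng = np.random.default_rng(2)
        feats, cohort = simulate_pairs(rng, 2000, [0.3])
        design = build_pair_differences(feats, cohort)
        res = refit_unpenalized([("f0", OVERALL)], design)
        row = res.table.loc[("f0", OVERALL)]
        assert abs(row["estimate"] - 0.3) < 3 * row["se"]


class TestExtendedComparison:
    def test_nesting_and_df(self):
        rng = np.random.default_rng(3)
        feats, cohort = simulate_pairs(
            rng, 300, [0.5, 0.0], types=["A", "B", "C"] * 100
        )
        design = build_pair_differences(feats, cohort)
        support = [("f0", OVERALL), ("f0", "B")]
        tab = extended_typespecific_comparison(support, design)
        assert list(tab.index) == ["f0"]
        row = tab.loc["f0"]
        assert row["loglik_extended"] >= row["loglik_restricted"] - 1e-10
        assert row["df"] == 3 - (1 + 1)
        assert 0 <= row["pvalue"] <= 1

    def test_no_overall_terms_empty(self):
        rng = np.random.default_rng(4)
        feats, cohort = simulate_pairs(rng, 50, [0.0])
        design = build_pair_differences(feats, cohort)
        assert extended_typespecific_comparison([("f0", "T1")], design).empty

    def test_power_against_omitted_deviation(self):
        """A strong deviation missing from the support is detected."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(50 + seed)
            n = 500
            types = ["A", "B"] * (n // 2)
            X = rng.standard_normal((n, 2, 1))
            beta = np.where(np.array(types) == "A", 0.3 + 0.5, 0.3)  # dev on A
            eta = X[:, :, 0] * beta[:, None]
            case_first = rng.random(n) < 1 / (1 + np.exp(-(eta[:, 0] - eta[:, 1])))
            ids = np.array([f"s{i}" for i in range(2 * n)]).reshape(n, 2)
            case = np.where(case_first, ids[:, 0], ids[:, 1])
            ctrl = np.where(case_first, ids[:, 1], ids[:, 0])
            feats = pd.DataFrame(
                X.reshape(-1, 1), index=ids.reshape(-1), columns=["f0"]
            )
            cohort = build_cohort(list(zip(case, ctrl)), cancer_type=types)
            design = build_pair_differences(feats, cohort)
            tab = extended_typespecific_comparison([("f0", OVERALL)], design)
            hits += tab.loc["f0", "pvalue"] < 0.05
        assert hits >= 8


class TestSplineLinearity:
    def test_basis_has_linear_leading_column_and_4_df(self):
        x = np.random.default_rng(5).standard_normal(500)
        B = natural_spline_basis(x)
        assert B.shape[1] == 4
        np.testing.assert_array_equal(B[:, 0], x)

    def test_nesting_holds(self):
        rng = np.random.default_rng(6)
        feats, cohort = simulate_pairs(rng, 300, [0.5])
        out = spline_linearity_test(feats["f0"], cohort)
        assert out["loglik_spline"] >= out["loglik_linear"] - 1e-10
        assert out["df"] == 3

    def test_insufficient_unique_values_rejected(self):
        rng = np.random.default_rng(7)
        feats, cohort = simulate_pairs(rng, 40, [0.0])
        feats["f0"] = np.repeat([0.0, 1.0], len(feats) // 2)
        with pytest.raises(ValueError, match="distinct"):
            spline_linearity_test(feats["f0"], cohort)

    def test_power_for_quadratic_effect(self):
        """Strong curvature is flagged in most replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(80 + seed)
            n = 1000
            X = rng.standard_normal((n, 2))
            eta = 0.8 * X**2  # purely quadratic risk
            case_first = rng.random(n) < 1 / (1 + np.exp(-(eta[:, 0] - eta[:, 1])))
            ids = np.array([f"s{i}" for i in range(2 * n)]).reshape(n, 2)
            case = np.where(case_first, ids[:, 0], ids[:, 1])
            ctrl = np.where(case_first, ids[:, 1], ids[:, 0])
            feats = pd.DataFrame({"f0": X.reshape(-1)}, index=ids.reshape(-1))
            cohort = build_cohort(list(zip(case, ctrl)))
            hits += spline_linearity_test(feats["f0"], cohort)["pvalue"] < 0.05
        assert hits >= 8


class TestBmiEffectModification:
    def _cohort(self, rng, n=400, interaction=0.0):
        X = rng.standard_normal((n, 2))
        bmi = 26 + 3.5 * rng.standard_normal((n, 2))
        eta = 0.3 * X + 0.03 * (bmi - 26) + interaction * X * (bmi - 26)
        case_first = rng.random(n) < 1 / (1 + np.exp(-(eta[:, 0] - eta[:, 1])))
        ids = np.array([f"s{i}" for i in range(2 * n)]).reshape(n, 2)
        case = np.where(case_first, ids[:, 0], ids[:, 1])
        ctrl = np.where(case_first, ids[:, 1], ids[:, 0])
        feats = pd.DataFrame({"f0": X.reshape(-1)}, index=ids.reshape(-1))
        cohort = build_cohort(list(zip(case, ctrl)), bmi=bmi.reshape(-1))
        return feats, cohort

    def test_centering_invariance(self):
        rng = np.random.default_rng(8)
        feats, cohort = self._cohort(rng)
        p1 = bmi_effect_modification(feats["f0"], cohort)["pvalue"]
        shifted = cohort.copy()
        shifted.samples["bmi"] = shifted.samples["bmi"] - 26.0
        p2 = bmi_effect_modification(feats["f0"], shifted)["pvalue"]
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_power_for_strong_interaction(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(120 + seed)
            feats, cohort = self._cohort(rng, n=800, interaction=0.12)
            hits += bmi_effect_modification(feats["f0"], cohort)["pvalue"] < 0.05
        assert hits >= 8

    def test_degenerate_feature_rejected(self):
        rng = np.random.default_rng(9)
        feats, cohort = self._cohort(rng, n=50)
        feats["f0"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            bmi_effect_modification(feats["f0"], cohort)


class TestSensitivityRefit:
    def test_followup_filter_counting(self):
        rng = np.random.default_rng(10)
        feats, cohort = simulate_pairs(rng, 3, [0.0])
        cohort.pairs["follow_up_years"] = [1.0, 3.0, 8.0]
        res = sensitivity_refit(
            SensitivitySpec(filter="exclude_followup_lt_2y"),
            [("f0", OVERALL)], cohort, feats,
        )
        assert res.n_pairs == 2

    def test_none_spec_equals_plain_refit(self):
        rng = np.random.default_rng(11)
        feats, cohort = simulate_pairs(rng, 200, [0.4])
        design = build_pair_differences(feats, cohort)
        base = refit_unpenalized([("f0", OVERALL)], design)
        sens = sensitivity_refit(SensitivitySpec(), [("f0", OVERALL)], cohort, feats)
        pd.testing.assert_frame_equal(base.table, sens.table)

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError, match="unknown filter"):
            SensitivitySpec(filter="bogus")

    def test_extra_covariates_enter_as_differences(self):
        rng = np.random.default_rng(12)
        feats, cohort = simulate_pairs(rng, 150, [0.4])
        cohort.samples["waist"] = rng.normal(90, 10, len(cohort.samples))
        res = sensitivity_refit(
            SensitivitySpec(extra_covariates=["waist"]),
            [("f0", OVERALL)], cohort, feats,
        )
        assert ("waist", "covariate") in res.table.index

    def test_emptied_type_drops_term_with_warning(self):
        rng = np.random.default_rng(13)
        feats, cohort = simulate_pairs(rng, 40, [0.2], types=["A", "B"] * 20)
        cohort.pairs.loc[cohort.pairs["cancer_type"] == "B", "follow_up_years"] = 1.0
        cohort.pairs.loc[cohort.pairs["cancer_type"] == "A", "follow_up_years"] = 9.0
        with pytest.warns(UserWarning, match="emptied type"):
            res = sensitivity_refit(
                SensitivitySpec(filter="exclude_followup_lt_7y"),
                [("f0", OVERALL), ("f0", "B")], cohort, feats,
            )
        assert ("f0", "B") not in res.table.index

    def test_reverse_causation_attenuation(self):
        """Effect confined to short-follow-up pairs attenuates by >50%
        after excluding the first 2 years."""
        rng = np.random.default_rng(14)
        n = 1500
        fu = rng.uniform(0.0, 10.0, n)
        X = rng.standard_normal((n, 2))
        beta = np.where(fu < 2.0, 1.2, 0.0)  # reverse causation only
        eta = X * beta[:, None]
        case_first = rng.random(n) < 1 / (1 + np.exp(-(eta[:, 0] - eta[:, 1])))
        ids = np.array([f"s{i}" for i in range(2 * n)]).reshape(n, 2)
        case = np.where(case_first, ids[:, 0], ids[:, 1])
        ctrl = np.where(case_first, ids[:, 1], ids[:, 0])
        feats = pd.DataFrame({"f0": X.reshape(-1)}, index=ids.reshape(-1))
        cohort = build_cohort(list(zip(case, ctrl)), follow_up=list(fu))
        full = sensitivity_refit(SensitivitySpec(), [("f0", OVERALL)], cohort, feats)
        excl = sensitivity_refit(
            SensitivitySpec(filter="exclude_followup_lt_2y"),
            [("f0", OVERALL)], cohort, feats,
        )
        b_full = full.table.loc[("f0", OVERALL), "estimate"]
        b_excl = excl.table.loc[("f0", OVERALL), "estimate"]
        assert abs(b_excl) < 0.5 * abs(b_full)


class TestUnivariate:
    def test_singleton_support_equivalence(self):
        """Single feature, single type: identical to the refit on that
        singleton support (both residualize on BMI)."""
        rng = np.random.default_rng(15)
        feats, cohort = simulate_pairs(rng, 200, [0.5], bmi_sd=3.0, bmi_log_or=0.05)
        tab = univariate_clogit(feats, cohort, bmi_adjust="residualize")
        from pancanmet.dslasso import residualize_on_bmi

        design = build_pair_differences(residualize_on_bmi(feats, cohort), cohort)
        ref = refit_unpenalized([("f0", OVERALL)], design)
        row = tab[(tab["feature"] == "f0") & (tab["cancer_type"] == "T1")].iloc[0]
        assert row["log_or"] == pytest.approx(
            ref.table.loc[("f0", OVERALL), "estimate"], abs=1e-10
        )

    def test_null_calibration(self):
        """Across null features the p < 0.05 rate is ~5%."""
        rng = np.random.default_rng(16)
        feats, cohort = simulate_pairs(rng, 300, [0.0] * 40, bmi_sd=3.0)
        tab = univariate_clogit(feats, cohort)
        pooled = tab[tab["cancer_type"] == "pooled"]
        rate = (pooled["pvalue"] < 0.05).mean()
        assert rate <= 0.15  # binomial(40, .05): P(>6 hits) tiny

    def test_pooled_gains_power_over_per_type(self):
        """A shared effect: pooled p below each per-type p in most runs."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            feats, cohort = simulate_pairs(
                rng, 600, [0.35], types=["A", "B", "C"] * 200, bmi_sd=3.0
            )
            tab = univariate_clogit(feats, cohort).set_index("cancer_type")
            pooled_p = tab.loc["pooled", "pvalue"]
            wins += (pooled_p < tab.drop("pooled")["pvalue"]).all()
        assert wins >= 9

    def test_qvalues_within_type(self):
        rng = np.random.default_rng(17)
        feats, cohort = simulate_pairs(rng, 100, [0.0, 0.0, 0.0], bmi_sd=3.0)
        tab = univariate_clogit(feats, cohort)
        grp = tab[tab["cancer_type"] == "T1"]
        assert (grp["qvalue"] >= grp["pvalue"] - 1e-12).all()
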