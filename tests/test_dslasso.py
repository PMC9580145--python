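"""Data-shared lasso core: likelihood equivalences, design construction,
solver optimality, limiting cases, CV behaviour and the Model/Results API."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from conftest import build_cohort, simulate_pairs
from pancanmet import _solver
from pancanmet.dslasso import (
    OVERALL,
    DataSharedLasso,
    PairDiffDesign,
    build_datashared_design,
    build_pair_differences,
    make_type_stratified_folds,
    residualize_on_bmi,
    select_lambda,
)
from pancanmet.synth import make_fixture


def enumerated_conditional_loglik(Xcase, Xctrl, beta):
    """Brute-force 1:1 conditional likelihood: per pair
    exp(b'x_case) / (exp(b'x_case) + exp(b'x_ctrl)), summed in logs."""
    a = Xcase @ beta
    b = Xctrl @ beta
    return float(np.sum(a - np.logaddexp(a, b)))


def lbfgs_oracle(Z, lam, w):
    """Independent convex solver on the positive/negative split."""
    n, p = Z.shape

    def f(x):
        return _solver.objective(Z, x[:p] - x[p:], lam, w)

    def grad(x):
        beta = x[:p] - x[p:]
        g = -(Z.T @ (1.0 / (1.0 + np.exp(Z @ beta)))) / n
        return np.concatenate([g + lam * w, -g + lam * w])

    res = minimize(
        f, np.zeros(2 * p), jac=grad, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-12},
    )
    return res.fun, res.x[:p] - res.x[p:]


class TestResidualize:
    def test_uncorrelated_feature_is_centered(self):
        rng = np.random.default_rng(0)
        feats, cohort = simulate_pairs(rng, 200, [0.0], bmi_sd=3.0)
        # replace feature by something independent of BMI by construction
        out = residualize_on_bmi(feats, cohort)
        bmi = cohort.samples.loc[feats.index, "bmi"].values
        assert abs(np.corrcoef(out["f0"], bmi)[0, 1]) < 1e-10
        slope = np.polyfit(bmi, feats["f0"], 1)[0]
        approx_centered = feats["f0"] - feats["f0"].mean() - slope * (bmi - bmi.mean())
        np.testing.assert_allclose(out["f0"], approx_centered, atol=1e-10)

    def test_pure_bmi_feature_vanishes(self):
        rng = np.random.default_rng(1)
        feats, cohort = simulate_pairs(rng, 100, [0.0], bmi_sd=3.0)
        feats["f0"] = 2.0 * cohort.samples.loc[feats.index, "bmi"].values
        out = residualize_on_bmi(feats, cohort)
        np.testing.assert_allclose(out["f0"], 0.0, atol=1e-9)

    def test_constant_bmi_rejected(self):
        rng = np.random.default_rng(2)
        feats, cohort = simulate_pairs(rng, 50, [0.0], bmi_sd=0.0)
        with pytest.raises(ValueError, match="constant"):
            residualize_on_bmi(feats, cohort)


class TestPairDifferences:
    def test_single_pair_fixture(self):
        m, cohort = make_fixture("single_pair")
        feats = np.log(m.values)
        design = build_pair_differences(feats, cohort)
        np.testing.assert_allclose(design.D.iloc[0].values, [1.0, -1.0], atol=1e-12)

    def test_loglik_at_zero_is_coinflips(self):
        rng = np.random.default_rng(3)
        feats, cohort = simulate_pairs(rng, 17, [0.2, -0.1])
        design = build_pair_differences(feats, cohort)
        beta = pd.DataFrame(0.0, index=["T1"], columns=design.features)
        assert design.loglik(beta) == pytest.approx(17 * np.log(0.5), abs=1e-12)

    def test_equals_enumerated_conditional_likelihood(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            feats, cohort = simulate_pairs(rng, 6, [0.3, -0.2, 0.1])
            design = build_pair_differences(feats, cohort)
            beta = rng.standard_normal(3)
            ll = float(
                -np.sum(np.logaddexp(0.0, -(design.D.values @ beta)))
            )
            Xc = feats.loc[cohort.pairs["case_id"]].values
            Xk = feats.loc[cohort.pairs["control_id"]].values
            assert ll == pytest.approx(
                enumerated_conditional_loglik(Xc, Xk, beta), abs=1e-12
            )

    def test_incomplete_pair_rejected(self):
        rng = np.random.default_rng(5)
        feats, cohort = simulate_pairs(rng, 4, [0.0])
        with pytest.raises(ValueError, match="incomplete"):
            build_pair_differences(feats.iloc[:-1], cohort)


class TestDataSharedDesign:
    def test_row_structure(self):
        """p=2, K=2, type-2 pair with d = (d1, d2) -> (d1, d2, 0, 0, d1, d2)."""
        D = pd.DataFrame({"f0": [0.5, -1.0], "f1": [2.0, 0.25]}, index=["p0", "p1"])
        design = PairDiffDesign(D=D, type_of_pair=pd.Series(["T1", "T2"], index=D.index))
        ds = build_datashared_design(design, types=["T1", "T2"], penalty_mode="unit")
        assert ds.Z.shape == (2, 6)  # p * (K + 1)
        np.testing.assert_allclose(
            ds.Z.loc["p1"].values, [-1.0, 0.25, 0, 0, -1.0, 0.25]
        )
        np.testing.assert_allclose(
            ds.Z.loc["p0"].values, [0.5, 2.0, 0.5, 2.0, 0, 0]
        )
        assert (ds.penalty_factors == 1.0).all()

    def test_penalty_factors_scale_with_type_size(self):
        D = pd.DataFrame({"f0": np.ones(6)})
        tof = pd.Series(["A"] * 4 + ["B"] * 2, index=D.index)
        ds = build_datashared_design(PairDiffDesign(D, tof), penalty_mode="sqrt_nk")
        assert ds.penalty_factors[("f0", OVERALL)] == 1.0
        assert ds.penalty_factors[("f0", "A")] == pytest.approx(np.sqrt(4 / 3))
        assert ds.penalty_factors[("f0", "B")] == pytest.approx(np.sqrt(2 / 3))

    def test_empty_type_rejected(self):
        D = pd.DataFrame({"f0": [1.0]})
        tof = pd.Series(["A"], index=D.index)
        with pytest.raises(ValueError, match="empty"):
            build_datashared_design(PairDiffDesign(D, tof), types=["A", "B"])


class TestSolver:
    def test_lambda_max_gives_exact_zero(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((30, 4))
        w = np.array([1.0, 2.0, 0.5, 1.0])
        lmax = _solver.lambda_max(Z, w)
        beta, _ = _solver.fit_penalized(Z, lmax * 1.000001, w)
        assert np.all(beta == 0.0)
        beta2, _ = _solver.fit_penalized(Z, lmax * 0.9, w)
        assert np.any(beta2 != 0.0)

    def test_matches_generic_convex_solver(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            Z = rng.standard_normal((25, 4))
            w = rng.uniform(0.5, 2.0, 4)
            lam = rng.uniform(0.01, 0.1)
            beta, diag = _solver.fit_penalized(Z, lam, w)
            f_oracle, _ = lbfgs_oracle(Z, lam, w)
            assert _solver.objective(Z, beta, lam, w) <= f_oracle + 1e-8
            assert diag["kkt"] < 1e-6

    def test_infinite_deviation_penalty_reduces_to_plain_lasso(self):
        """K=1 with deviation penalty -> infinity equals the lasso on D."""
        rng = np.random.default_rng(8)
        D = rng.standard_normal((60, 3))
        Z = np.hstack([D, D])  # K = 1: overall block then one deviation block
        lam = 0.03
        w = np.concatenate([np.ones(3), np.full(3, np.inf)])
        beta_ds, _ = _solver.fit_penalized(Z, lam, w)
        beta_plain, _ = _solver.fit_penalized(D, lam, np.ones(3))
        np.testing.assert_allclose(beta_ds[:3], beta_plain, atol=1e-6)
        np.testing.assert_allclose(beta_ds[3:], 0.0, atol=1e-12)

    def test_support_monotone_on_orthogonal_design(self):
        """Warm-started path over decreasing lambda on orthogonal columns."""
        n, p = 64, 8
        base = np.linalg.qr(np.random.default_rng(9).standard_normal((n, p)))[0]
        signal = np.linspace(0.2, 2.0, p)
        Z = base * signal * np.sqrt(n)
        lams = _solver.lambda_path(_solver.lambda_max(Z, np.ones(p)), 20, 1e-2)
        betas = _solver.fit_path(Z, lams)
        sizes = (np.abs(betas) > 1e-8).sum(axis=1)
        assert np.all(np.diff(sizes) >= 0)

    def test_unpenalized_matches_conditional_logit_oracle(self):
        """lambda=0, K=1: equals statsmodels ConditionalLogit estimates."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(10)
        feats, cohort = simulate_pairs(rng, 80, [0.5, -0.3, 0.0])
        design = build_pair_differences(feats, cohort)
        beta, _ = _solver.fit_penalized(design.D.values, 0.0, np.ones(3))
        endog = np.r_[np.ones(80), np.zeros(80)]
        exog = np.vstack(
            [feats.loc[cohort.pairs["case_id"]].values,
             feats.loc[cohort.pairs["control_id"]].values]
        )
        groups = np.r_[np.arange(80), np.arange(80)]
        sm_fit = ConditionalLogit(endog, exog, groups=groups).fit(
            method="newton", disp=False, maxiter=500
        )
        np.testing.assert_allclose(beta, sm_fit.params, atol=1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            _solver.fit_penalized(np.ones((3, 1)), -0.1)


class TestLambdaSelection:
    def test_folds_stratified_and_deterministic(self):
        tof = pd.Series(["A"] * 20 + ["B"] * 30)
        f1 = make_type_stratified_folds(tof, 5, seed=3)
        f2 = make_type_stratified_folds(tof, 5, seed=3)
        np.testing.assert_array_equal(f1, f2)
        for t, n in (("A", 20), ("B", 30)):
            counts = np.bincount(f1[(tof == t).values], minlength=5)
            assert counts.max() - counts.min() <= 1

    def test_tiny_type_rejected(self):
        tof = pd.Series(["A"] * 10 + ["B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            make_type_stratified_folds(tof, 5, seed=0)

    def test_same_seed_same_lambda(self):
        rng = np.random.default_rng(11)
        feats, cohort = simulate_pairs(rng, 120, [0.4, 0.0], types=["A", "B"] * 60)
        design = build_datashared_design(build_pair_differences(feats, cohort))
        lam1 = select_lambda(design, folds=4, seed=9)
        lam2 = select_lambda(design, folds=4, seed=9)
        assert lam1 == lam2

    def test_pure_noise_selects_near_null_model(self):
        """Under the global null the CV curve is flat: the deviance at
        lambda_max (null model) is within 2 SE of the CV minimum."""
        rng = np.random.default_rng(12)
        feats, cohort = simulate_pairs(rng, 150, [0.0] * 4)
        model = DataSharedLasso(feats, cohort, residualize_bmi=False)
        cv = model.cross_validate(folds=5, seed=1)
        i_min = int(np.argmin(cv.mean_deviance))
        assert cv.mean_deviance[0] <= cv.mean_deviance[i_min] + 2 * cv.se_deviance[i_min]

    def test_strong_signal_recovered_at_cv_lambda(self):
        """|log-OR| = 1 at n=500 pairs: the signal feature enters the
        support at the CV lambda in >= 19/20 replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            feats, cohort = simulate_pairs(rng, 500, [1.0, 0.0, 0.0])
            model = DataSharedLasso(feats, cohort, residualize_bmi=False)
            res = model.fit(cv_folds=4, seed=seed, n_lambdas=20, min_ratio=0.05)
            hits += ("f0", OVERALL) in set(res.support)
        assert hits >= 19


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(13)
    feats, cohort = simulate_pairs(
        rng, 400, [0.6, -0.5, 0.0, 0.0], types=["A", "B"] * 200, bmi_sd=2.0
    )
    model = DataSharedLasso(feats, cohort)
    return model.fit(cv_folds=4, seed=2, n_lambdas=20, min_ratio=0.05)


class TestResultsAPI:
    def test_type_log_ors_is_mu_plus_delta(self, fitted):
        tab = fitted.type_log_ors()
        for t in fitted.model.types:
            np.testing.assert_allclose(
                tab.loc[t].values, (fitted.mu + fitted.delta.loc[t]).values, atol=1e-12
            )

    def test_support_tolerance(self, fitted):
        for term in fitted.support:
            assert abs(fitted.params[term]) > 1e-8

    def test_kkt_certificate(self, fitted):
        assert fitted.diagnostics["kkt"] < 1e-6

    def test_summary_mentions_selected_terms(self, fitted):
        text = fitted.summary()
        assert "lambda" in text and "f0" in text

    def test_coefficient_table_structure(self, fitted):
        tab = fitted.coefficient_table()
        assert tab.shape == (4, 2)
        sup_feats = {f for f, lvl in fitted.support}
        zero_rows = tab.index[(tab == 0).all(axis=1)]
        assert sup_feats.isdisjoint(zero_rows)

    def test_serialization_roundtrip(self, fitted, tmp_path):
        path = tmp_path / "fit.json"
        fitted.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["lambda"] == fitted.lambda_
        assert set(payload["mu"]) == set(fitted.feature_names)


def test_null_cohorts_rarely_select_any_given_term():
    """Under the global null, the CV data-shared lasso selects any given
    term in at most 20% of 50 independent synthetic replicates."""
    from pancanmet.synth import SynthConfig, generate_cohort

    counts = {}
    R = 50
    for seed in range(R):
        cfg = SynthConfig(
            n_pairs_per_type={"A": 150, "B": 150}, n_metabolites=6, seed=1000 + seed
        )
        m, cohort, _ = generate_cohort(cfg)
        model = DataSharedLasso(np.log(m.values), cohort)
        res = model.fit(seed=seed, cv_folds=4, n_lambdas=15, min_ratio=0.1)
        for t in res.support:
            counts[t] = counts.get(t, 0) + 1
    assert max(counts.values(), default=0) / R <= 0.20
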