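"""Data-shared lasso on matched case-control conditional likelihoods.

For 1:1 matched pairs the conditional logistic likelihood factorises over
pairs as ``sigma(beta_k' d_i)`` where ``d_i`` is the case-minus-control
feature difference of pair ``i`` and ``beta_k`` the coefficient vector of
the pair's cancer type ``k``.  The data-shared lasso parameterises

    beta_k = mu + delta_k

with one shared (overall) vector ``mu`` and per-type deviation vectors
``delta_k``, stacked into an augmented design: the row of a type-``k``
pair carries ``d_i`` in the overall block and in deviation block ``k``,
zeros elsewhere.  An L1 penalty with per-block penalty factors then
decides, per feature, whether the overall association is null and whether
any type deviates from it.

The user-facing objects follow the Model/Results convention:

>>> model = DataSharedLasso(features, cohort)
>>> res = model.fit(seed=1)          # pair-stratified CV picks lambda
>>> res.summary()
>>> refit = res.refit_unpenalized()  # lasso-OLS hybrid, Wald CIs
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _solver
from .containers import PairedCohort

SUPPORT_TOL = 1e-8  # |beta| below this is a structural zero
OVERALL = "overall"


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------


def residualize_on_bmi(features: pd.DataFrame, cohort: PairedCohort) -> pd.DataFrame:
    """Replace each feature by its residual from a simple linear regression
    on BMI, fitted over all samples of the analysis set."""
    bmi = cohort.samples.loc[features.index, "bmi"].astype(float).values
    if np.ptp(bmi) == 0:
        raise ValueError("BMI is constant: residualization is degenerate")
    X = np.column_stack([np.ones_like(bmi), bmi])
    coef, *_ = np.linalg.lstsq(X, features.values, rcond=None)
    resid = features.values - X @ coef
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


@dataclass
class PairDiffDesign:
    """Case-minus-control feature differences, one row per matched pair."""

    D: pd.DataFrame  # pairs x features
    type_of_pair: pd.Series  # pair -> cancer type

    @property
    def features(self) -> list:
        return list(self.D.columns)

    @property
    def types(self) -> list:
        return list(pd.unique(self.type_of_pair))

    def loglik(self, beta_by_type: pd.DataFrame) -> float:
        """Conditional log-likelihood at type-specific coefficients
        (DataFrame types x features)."""
        eta = np.einsum(
            "ij,ij->i",
            self.D.values,
            beta_by_type.loc[self.type_of_pair].values,
        )
        return float(-np.sum(np.logaddexp(0.0, -eta)))


def build_pair_differences(
    features: pd.DataFrame, cohort: PairedCohort
) -> PairDiffDesign:
    """Assemble the pair-difference design (no intercept concept exists)."""
    missing = set(cohort.sample_ids) - set(features.index)
    if missing:
        raise ValueError(f"incomplete pairs: features missing for {sorted(missing)[:5]}")
    case = features.loc[cohort.pairs["case_id"]].values
    ctrl = features.loc[cohort.pairs["control_id"]].values
    D = pd.DataFrame(case - ctrl, index=cohort.pairs.index, columns=features.columns)
    return PairDiffDesign(D=D, type_of_pair=cohort.pairs["cancer_type"].copy())


@dataclass
class DataSharedDesign:
    """Stacked overall + per-type deviation design with penalty factors."""

    Z: pd.DataFrame  # pairs x (p * (K + 1)); MultiIndex columns (feature, level)
    penalty_factors: pd.Series
    type_of_pair: pd.Series
    types: list

    @property
    def features(self) -> list:
        seen = []
        for f, lvl in self.Z.columns:
            if lvl == OVERALL:
                seen.append(f)
        return seen


def deviation_penalty_factors(
    type_counts: pd.Series, mode: str = "sqrt_nk"
) -> pd.Series:
    """Per-type deviation penalty factors r_k.

    ``sqrt_nk`` scales each type's deviation penalty by sqrt(n_k / n_bar)
    (larger types may support deviations on more evidence, smaller types
    are shielded from spurious ones); ``unit`` uses r_k = 1.
    """
    if mode == "unit":
        return pd.Series(1.0, index=type_counts.index)
    if mode == "sqrt_nk":
        return np.sqrt(type_counts / type_counts.mean())
    raise ValueError(f"unknown penalty mode {mode!r}")


def build_datashared_design(
    design: PairDiffDesign,
    types: list | None = None,
    penalty_mode: str = "sqrt_nk",
) -> DataSharedDesign:
    """Stack the overall block and K deviation blocks.

    The row of a type-k pair holds its difference vector in the overall
    block and in deviation block k, zeros elsewhere; the column count is
    p * (K + 1).
    """
    types = list(types) if types is not None else sorted(design.types)
    counts = design.type_of_pair.value_counts()
    empty = [t for t in types if counts.get(t, 0) == 0]
    if empty:
        raise ValueError(f"empty cancer type(s): {empty}")
    p = len(design.features)
    n = len(design.D)
    K = len(types)
    Zv = np.zeros((n, p * (K + 1)))
    Zv[:, :p] = design.D.values
    tindex = {t: i for i, t in enumerate(types)}
    block = np.array([tindex[t] for t in design.type_of_pair])
    rows = np.arange(n)
    for j in range(p):
        Zv[rows, p * (1 + block) + j] = design.D.values[:, j]
    cols = pd.MultiIndex.from_tuples(
        [(f, OVERALL) for f in design.features]
        + [(f, t) for t in types for f in design.features],
        names=["feature", "level"],
    )
    Z = pd.DataFrame(Zv, index=design.D.index, columns=cols)
    r = deviation_penalty_factors(counts.reindex(types), penalty_mode)
    pf = pd.Series(1.0, index=cols)
    for t in types:
        pf.loc[pd.IndexSlice[:, t]] = r[t]
    return DataSharedDesign(Z=Z, penalty_factors=pf, type_of_pair=design.type_of_pair, types=types)


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------


def make_type_stratified_folds(
    type_of_pair: pd.Series, folds: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Pair-level fold assignment, stratified by cancer type."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assign = np.empty(len(type_of_pair), dtype=np.int64)
    codes = type_of_pair.values
    for t in pd.unique(codes):
        idx = np.where(codes == t)[0]
        if len(idx) < 2:
            raise ValueError(f"cancer type {t!r} has fewer than 2 pairs; cannot stratify CV")
        if len(idx) < folds:
            warnings.warn(f"cancer type {t!r} has fewer pairs than folds")
        perm = rng.permutation(len(idx))
        assign[idx[perm]] = np.arange(len(idx)) % folds
    return assign


@dataclass
class CVResult:
    lams: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lam_min: float
    lam_1se: float
    folds: int

    def selected(self, rule: str = "1se") -> float:
        if rule == "min":
            return self.lam_min
        if rule == "1se":
            return self.lam_1se
        raise ValueError(f"unknown CV rule {rule!r}")


def cross_validate_lambda(
    Z: np.ndarray,
    penalty_factors: np.ndarray,
    type_of_pair: pd.Series,
    folds: int = 10,
    seed: int | np.random.Generator = 0,
    n_lambdas: int = 30,
    min_ratio: float = 0.03,
    kkt_tol: float = 1e-7,
) -> CVResult:
    """Pair-stratified K-fold CV of the conditional-likelihood deviance."""
    lmax = _solver.lambda_max(Z, penalty_factors)
    lams = _solver.lambda_path(lmax * 1.0001, n_lambdas, min_ratio)
    assign = make_type_stratified_folds(type_of_pair, folds, seed)
    dev = np.zeros((folds, len(lams)))
    for f in range(folds):
        train = assign != f
        test = ~train
        betas = _solver.fit_path(
            np.ascontiguousarray(Z[train]), lams, penalty_factors, kkt_tol=kkt_tol
        )
        eta = Z[test] @ betas.T  # n_test x n_lams
        dev[f] = 2.0 * np.mean(np.logaddexp(0.0, -eta), axis=0)
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean))
    thresh = mean[i_min] + se[i_min]
    i_1se = int(np.argmax(mean <= thresh))  # largest lambda within one SE
    return CVResult(
        lams=lams,
        mean_deviance=mean,
        se_deviance=se,
        lam_min=float(lams[i_min]),
        lam_1se=float(lams[i_1se]),
        folds=folds,
    )


def select_lambda(
    design: DataSharedDesign,
    folds: int = 10,
    seed: int | np.random.Generator = 0,
    rule: str = "1se",
    **kwargs,
) -> float:
    """Pick lambda by pair-stratified cross-validated deviance."""
    cv = cross_validate_lambda(
        np.ascontiguousarray(design.Z.values),
        design.penalty_factors.values,
        design.type_of_pair,
        folds=folds,
        seed=seed,
        **kwargs,
    )
    return cv.selected(rule)


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------


class DataSharedLasso:
    """Data-shared lasso model for matched case-control pairs.

    Parameters
    ----------
    features : DataFrame (samples x features)
        Log-scale metabolite features (cluster representatives and isolated
        metabolites) for every sample of the cohort.
    cohort : PairedCohort
    residualize_bmi : bool
        Replace features by their residuals on BMI before differencing.
    standardize : bool
        Scale features to unit variance on the control samples, so
        coefficients are log-ORs per control SD.
    penalty_mode : str
        Deviation-block penalty factors: ``sqrt_nk`` (default) or ``unit``.
    types : list, optional
        Cancer-type order (default: sorted).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        cohort: PairedCohort,
        residualize_bmi: bool = True,
        standardize: bool = True,
        penalty_mode: str = "sqrt_nk",
        types: list | None = None,
    ):
        features = features.loc[cohort.sample_ids]
        if residualize_bmi:
            features = residualize_on_bmi(features, cohort)
        if standardize:
            sds = features.loc[cohort.control_ids].std(ddof=1)
            if (sds == 0).any():
                bad = list(sds.index[sds == 0])[:5]
                raise ValueError(f"zero control-sample variance for features {bad}")
            features = features / sds
            self.feature_scales = sds
        else:
            self.feature_scales = pd.Series(1.0, index=features.columns)
        self.features = features
        self.cohort = cohort
        self.penalty_mode = penalty_mode
        self.pair_design = build_pair_differences(features, cohort)
        self.design = build_datashared_design(
            self.pair_design, types=types, penalty_mode=penalty_mode
        )

    @classmethod
    def from_dataframe(
        cls, features: pd.DataFrame, pairs: pd.DataFrame, samples: pd.DataFrame, **kwargs
    ) -> "DataSharedLasso":
        return cls(features, PairedCohort(pairs, samples), **kwargs)

    @property
    def types(self) -> list:
        return self.design.types

    def lambda_max(self) -> float:
        return _solver.lambda_max(self.design.Z.values, self.design.penalty_factors.values)

    def cross_validate(self, folds: int = 10, seed=0, **kwargs) -> CVResult:
        return cross_validate_lambda(
            np.ascontiguousarray(self.design.Z.values),
            self.design.penalty_factors.values,
            self.design.type_of_pair,
            folds=folds,
            seed=seed,
            **kwargs,
        )

    def fit(
        self,
        lam: float | None = None,
        cv_folds: int = 10,
        cv_rule: str = "1se",
        seed: int | np.random.Generator = 0,
        n_lambdas: int = 30,
        min_ratio: float = 0.03,
        kkt_tol: float = 1e-8,
    ) -> "DataSharedLassoResults":
        """Fit at ``lam``, or at the CV-selected lambda when ``lam`` is None."""
        cv = None
        if lam is None:
            cv = self.cross_validate(
                folds=cv_folds,
                seed=seed,
                n_lambdas=n_lambdas,
                min_ratio=min_ratio,
            )
            lam = cv.selected(cv_rule)
        Z = np.ascontiguousarray(self.design.Z.values)
        pf = self.design.penalty_factors.values
        # warm-start through a short path down to the target lambda
        lmax = _solver.lambda_max(Z, pf)
        if lam < lmax:
            pre = np.geomspace(lmax, lam, 8)[:-1]
            beta = _solver.fit_path(Z, pre, pf, kkt_tol=1e-6)[-1]
        else:
            beta = None
        beta, diag = _solver.fit_penalized(Z, lam, pf, beta0=beta, kkt_tol=kkt_tol)
        return DataSharedLassoResults(self, beta, float(lam), diag, cv=cv)


class DataSharedLassoResults:
    """Fitted data-shared lasso: overall vector mu, deviations delta_k."""

    def __init__(self, model: DataSharedLasso, beta: np.ndarray, lam: float,
                 diagnostics: dict, cv: CVResult | None = None):
        self.model = model
        self.params = pd.Series(beta, index=model.design.Z.columns, name="coef")
        self.lambda_ = lam
        self.diagnostics = diagnostics
        self.cv = cv
        self.penalty_factors = model.design.penalty_factors

    # ------------------------------------------------------------- pieces
    @property
    def feature_names(self) -> list:
        return self.model.pair_design.features

    @property
    def mu(self) -> pd.Series:
        """Overall log-ORs (per control SD of the feature)."""
        out = self.params.xs(OVERALL, level="level")
        return out.reindex(self.feature_names)

    @property
    def delta(self) -> pd.DataFrame:
        """Type-specific deviation log-ORs (types x features)."""
        rows = {}
        for t in self.model.types:
            rows[t] = self.params.xs(t, level="level").reindex(self.feature_names)
        return pd.DataFrame(rows).T

    @property
    def support(self) -> list:
        """Nonzero terms as (feature, level) tuples; level is ``overall``
        or a cancer type."""
        nz = self.params[self.params.abs() > SUPPORT_TOL]
        return list(nz.index)

    def type_log_ors(self) -> pd.DataFrame:
        """Entry (k, j) = mu_j + delta_kj (types x features)."""
        return self.delta.add(self.mu, axis=1)

    def classify_terms(self) -> pd.DataFrame:
        """Per feature: overall-null/nonnull plus deviating types."""
        sup = set(self.support)
        rows = []
        for f in self.feature_names:
            devs = [t for t in self.model.types if (f, t) in sup]
            rows.append(
                {
                    "feature": f,
                    "overall_nonnull": (f, OVERALL) in sup,
                    "deviating_types": ",".join(devs),
                }
            )
        return pd.DataFrame(rows).set_index("feature")

    def loglik(self) -> float:
        return _solver.loglik(self.model.design.Z.values, self.params.values)

    # ------------------------------------------------------- downstream
    def refit_unpenalized(self, **kwargs):
        from .postfit import refit_unpenalized

        return refit_unpenalized(self.support, self.model.pair_design, **kwargs)

    def bootstrap_stability(self, B: int = 100, seed: int = 0, **kwargs):
        from .stability import bootstrap_select

        return bootstrap_select(
            self.model.features,
            self.model.cohort,
            B=B,
            seed=seed,
            penalty_mode=self.model.penalty_mode,
            residualize_bmi=False,  # model features are already residualized
            standardize=False,
            **kwargs,
        )

    # ------------------------------------------------------------ output
    def summary(self) -> str:
        sup = self.support
        lines = [
            "Data-shared lasso (conditional logistic, 1:1 matched pairs)",
            "=" * 62,
            f"pairs: {len(self.model.pair_design.D)}   features: {len(self.feature_names)}"
            f"   cancer types: {len(self.model.types)}",
            f"lambda: {self.lambda_:.5g}   penalty mode: {self.model.penalty_mode}"
            f"   KKT residual: {self.diagnostics['kkt']:.2e}",
            f"selected terms: {len(sup)} "
            f"({sum(1 for _, l in sup if l == OVERALL)} overall, "
            f"{sum(1 for _, l in sup if l != OVERALL)} deviations)",
            "-" * 62,
            f"{'feature':<28}{'level':<12}{'log-OR/SD':>10}{'OR':>8}",
        ]
        for f, lvl in sup:
            b = self.params[(f, lvl)]
            lines.append(f"{f:<28}{lvl:<12}{b:>10.4f}{np.exp(b):>8.3f}")
        if not sup:
            lines.append("(empty support)")
        return "\n".join(lines)

    def coefficient_table(self) -> pd.DataFrame:
        """Feature x type table of selected-term log-ORs (0 = not selected)."""
        sup = set(self.support)
        tab = pd.DataFrame(
            0.0, index=self.feature_names, columns=self.model.types
        )
        for f in self.feature_names:
            base = self.params[(f, OVERALL)] if (f, OVERALL) in sup else 0.0
            for t in self.model.types:
                dev = self.params[(f, t)] if (f, t) in sup else 0.0
                tab.loc[f, t] = base + dev
        return tab

    def plot_heatmap(self, ax=None):
        """Feature x type signed-effect matrix (inverse green, positive red)."""
        import matplotlib.pyplot as plt

        tab = self.coefficient_table()
        if ax is None:
            _, ax = plt.subplots(
                figsize=(max(6, 0.22 * len(tab)), 0.5 * len(tab.columns) + 1.5)
            )
        vmax = max(float(tab.abs().values.max()), 1e-6)
        im = ax.imshow(tab.T.values, cmap="PiYG_r", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_yticks(range(len(tab.columns)), tab.columns)
        ax.set_xticks(range(len(tab)), tab.index, rotation=90, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="log-OR per SD")
        return ax

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lambda": self.lambda_,
            "penalty_mode": self.model.penalty_mode,
            "types": list(self.model.types),
            "mu": self.mu.to_dict(),
            "delta": {t: row.dropna().to_dict() for t, row in self.delta.iterrows()},
            "support": [[f, lvl] for f, lvl in self.support],
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def extract_type_log_ors(fit: DataSharedLassoResults) -> pd.DataFrame:
    """Type-specific log-ORs mu_j + delta_kj of a fitted model."""
    return fit.type_log_ors()
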