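"""Post-selection estimation and secondary analyses.

After the data-shared lasso picks a support, associations are re-estimated
without penalty (lasso-OLS hybrid rationale): unpenalized conditional
logistic regression restricted to the selected columns, with Wald 95% CIs
flagged as post-selection inference.  On top of that refit the module
provides the secondary analyses: fully type-specific "extended" model
comparisons, natural-cubic-spline linearity checks, BMI effect
modification in an unmatched logistic model, sensitivity refits
(follow-up exclusions, hormone-user reintegration, extra covariates), and
the non-mutually-adjusted univariate comparison track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clogit import ClogitFit, fit_clogit, lrt_pvalue, natural_spline_basis, null_loglik
from .containers import PairedCohort
from .dslasso import OVERALL, PairDiffDesign, residualize_on_bmi


@dataclass
class RefitResult:
    """Unpenalized refit on a selected support (post-selection inference)."""

    table: pd.DataFrame  # index (feature, level); estimate/se/CI/OR columns
    loglik: float
    n_pairs: int
    post_selection: bool = True

    @property
    def empty(self) -> bool:
        return self.table.empty

    def __str__(self) -> str:
        head = (
            f"Unpenalized conditional logistic refit on {len(self.table)} selected "
            f"term(s), {self.n_pairs} pairs (post-selection: interpret with caution)"
        )
        return head + ("\n" + self.table.to_string() if not self.empty else "")


def reduced_design(support: list, design: PairDiffDesign) -> pd.DataFrame:
    """Pair-difference columns for the given (feature, level) terms.

    An ``overall`` term contributes the raw difference column; a
    type-specific term contributes the difference masked to that type's
    pairs (zero elsewhere).
    """
    cols = {}
    types = set(design.types)
    for f, lvl in support:
        if f not in design.D.columns:
            raise KeyError(f"unknown feature {f!r} in support")
        if lvl == OVERALL:
            cols[(f, lvl)] = design.D[f].values
        else:
            if lvl not in types:
                raise KeyError(f"unknown cancer type {lvl!r} in support")
            cols[(f, lvl)] = design.D[f].values * (design.type_of_pair == lvl).values
    out = pd.DataFrame(cols, index=design.D.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["feature", "level"])
    return out


def _fit_to_table(fit: ClogitFit, terms: list, alpha: float = 0.05) -> pd.DataFrame:
    lo, hi = fit.ci(alpha)
    ok = fit.estimable
    est = np.where(ok, fit.params, np.nan)
    se = np.where(ok, fit.se, np.nan)
    lo = np.where(ok, lo, np.nan)
    hi = np.where(ok, hi, np.nan)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
            "or": np.exp(est),
            "or_low": np.exp(lo),
            "or_high": np.exp(hi),
            "pvalue": np.where(ok, fit.wald_pvalues(), np.nan),
            "estimable": ok,
        },
        index=pd.MultiIndex.from_tuples(terms, names=["feature", "level"]),
    )


def refit_unpenalized(
    support: list, design: PairDiffDesign, alpha: float = 0.05
) -> RefitResult:
    """Lasso-OLS hybrid: maximum conditional likelihood on the selected
    columns with Wald CIs.  Empty support returns the null model."""
    if not support:
        return RefitResult(
            table=pd.DataFrame(
                columns=["estimate", "se", "ci_low", "ci_high", "or", "or_low",
                         "or_high", "pvalue", "estimable"]
            ),
            loglik=null_loglik(len(design.D)),
            n_pairs=len(design.D),
        )
    X = reduced_design(support, design)
    fit = fit_clogit(X.values)
    return RefitResult(
        table=_fit_to_table(fit, list(X.columns), alpha),
        loglik=fit.loglik,
        n_pairs=fit.n_pairs,
    )


# --------------------------------------------------------------------------
# extended fully type-specific comparison
# --------------------------------------------------------------------------


def extended_typespecific_comparison(
    support: list, design: PairDiffDesign
) -> pd.DataFrame:
    """Compare the selected model to 'extended' fully type-specific models.

    For every feature with a nonnull overall term, the extended model
    replaces that feature's overall + selected-deviation columns with K
    fully type-specific columns (the restricted model is nested in it).
    Returns one row per such feature with the likelihood-ratio statistic,
    its degrees of freedom and p-value, plus both log-likelihoods.
    """
    sup = list(support)
    overall_feats = [f for f, lvl in sup if lvl == OVERALL]
    if not overall_feats:
        return pd.DataFrame(
            columns=["feature", "lrt", "df", "pvalue", "loglik_restricted",
                     "loglik_extended", "estimable"]
        ).set_index("feature")
    X_r = reduced_design(sup, design)
    fit_r = fit_clogit(X_r.values)
    types = design.types
    rows = []
    for f in overall_feats:
        keep = [t for t in sup if t[0] != f]
        ext_terms = keep + [(f, t) for t in types]
        X_e = reduced_design(ext_terms, design)
        fit_e = fit_clogit(X_e.values)
        n_dev_selected = sum(1 for ff, lvl in sup if ff == f and lvl != OVERALL)
        df = len(types) - (1 + n_dev_selected)
        stat, p = lrt_pvalue(fit_e.loglik, fit_r.loglik, df)
        estimable = bool(fit_e.estimable.all() and fit_r.estimable.all())
        if not estimable:
            warnings.warn(
                f"extended model for {f!r} has non-estimable terms (sparse type?)"
            )
        rows.append(
            {
                "feature": f,
                "lrt": stat,
                "df": df,
                "pvalue": p,
                "loglik_restricted": fit_r.loglik,
                "loglik_extended": fit_e.loglik,
                "estimable": estimable,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# --------------------------------------------------------------------------
# spline linearity check
# --------------------------------------------------------------------------


def spline_linearity_test(
    feature: pd.Series,
    cohort: PairedCohort,
    adjust: pd.DataFrame | None = None,
    knot_quantiles: tuple = (0.25, 0.5, 0.75),
    boundary_quantiles: tuple = (0.05, 0.95),
) -> dict:
    """Departure-from-linearity LRT for one feature.

    A natural cubic spline basis (computed on the pooled sample values,
    then differenced within pairs) replaces the linear term; the spline
    model nests the linear one, and the LRT has (basis columns - 1)
    degrees of freedom.  ``adjust`` columns (per sample) enter both models
    as unpenalized difference terms.
    """
    x = feature.loc[cohort.sample_ids].astype(float)
    if x.nunique() < 6:
        raise ValueError("insufficient distinct values to place spline knots")
    B = natural_spline_basis(
        x.values, knot_quantiles=knot_quantiles, boundary_quantiles=boundary_quantiles
    )
    B = pd.DataFrame(B, index=x.index)
    Bd = B.loc[cohort.pairs["case_id"]].values - B.loc[cohort.pairs["control_id"]].values
    extra = None
    if adjust is not None:
        extra = (
            adjust.loc[cohort.pairs["case_id"]].values
            - adjust.loc[cohort.pairs["control_id"]].values
        )
    lin = Bd[:, :1] if extra is None else np.hstack([Bd[:, :1], extra])
    spl = Bd if extra is None else np.hstack([Bd, extra])
    fit_lin = fit_clogit(lin)
    fit_spl = fit_clogit(spl, start=np.concatenate([fit_lin.params[:1],
                                                    np.zeros(Bd.shape[1] - 1),
                                                    fit_lin.params[1:]]))
    df = Bd.shape[1] - 1
    stat, p = lrt_pvalue(fit_spl.loglik, fit_lin.loglik, df)
    return {
        "lrt": stat,
        "df": df,
        "pvalue": p,
        "loglik_linear": fit_lin.loglik,
        "loglik_spline": fit_spl.loglik,
    }


# --------------------------------------------------------------------------
# BMI effect modification (unmatched logistic)
# --------------------------------------------------------------------------


def _logistic_irls(X: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, float]:
    """Plain logistic MLE (with intercept column expected in X)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        pr = 1.0 / (1.0 + np.exp(-eta))
        g = X.T @ (y - pr)
        W = np.maximum(pr * (1 - pr), 1e-10)
        H = (X * W[:, None]).T @ X
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(g)) < 1e-9 * len(y):
            break
    ll = float(np.sum(y * np.log(pr + 1e-300) + (1 - y) * np.log(1 - pr + 1e-300)))
    return beta, ll


def bmi_effect_modification(
    feature: pd.Series,
    cohort: PairedCohort,
    batch_correct: bool = True,
) -> dict:
    """Interaction test between a feature and BMI, matching broken.

    The feature is batch-median centred (a simple location correction for
    batch effects), then an unmatched logistic model of case status on
    feature, BMI, feature x BMI, study indicators and the matching factors
    sex and age is compared by LRT to the same model without the
    interaction term.
    """
    ids = cohort.sample_ids
    x = feature.loc[ids].astype(float).copy()
    pairs = cohort.pairs
    batch_of = pd.concat(
        [
            pd.Series(pairs["batch"].values, index=pairs["case_id"]),
            pd.Series(pairs["batch"].values, index=pairs["control_id"]),
        ]
    ).loc[ids]
    study_of = pd.concat(
        [
            pd.Series(pairs["study"].values, index=pairs["case_id"]),
            pd.Series(pairs["study"].values, index=pairs["control_id"]),
        ]
    ).loc[ids]
    if batch_correct:
        x = x - x.groupby(batch_of.values).transform("median")
    if x.std() == 0:
        raise ValueError("degenerate feature after batch correction")
    bmi = cohort.samples.loc[ids, "bmi"].astype(float)
    y = np.zeros(len(ids))
    y[: len(pairs)] = 1.0  # sample_ids lists cases first
    inter = (x * bmi).values
    if np.std(inter) == 0:
        raise ValueError("degenerate interaction column")
    studies = pd.get_dummies(study_of, drop_first=True).astype(float)
    covs = [np.ones(len(ids)), x.values, bmi.values]
    names = ["const", "feature", "bmi"]
    if "sex" in cohort.samples.columns and cohort.samples.loc[ids, "sex"].nunique() > 1:
        covs.append((cohort.samples.loc[ids, "sex"] == "F").astype(float).values)
        names.append("sex_F")
    if "age" in cohort.samples.columns and cohort.samples.loc[ids, "age"].nunique() > 1:
        covs.append(cohort.samples.loc[ids, "age"].astype(float).values)
        names.append("age")
    X0 = np.column_stack(covs + [studies.values] if len(studies.columns) else covs)
    X1 = np.column_stack([X0, inter])
    _, ll0 = _logistic_irls(X0, y)
    _, ll1 = _logistic_irls(X1, y)
    stat, p = lrt_pvalue(ll1, ll0, 1)
    return {"lrt": stat, "df": 1, "pvalue": p}


# --------------------------------------------------------------------------
# sensitivity refits
# --------------------------------------------------------------------------

_FILTERS = {
    "none": lambda pairs: pd.Series(True, index=pairs.index),
    "exclude_followup_lt_2y": lambda pairs: pairs["follow_up_years"] >= 2.0,
    "exclude_followup_lt_7y": lambda pairs: pairs["follow_up_years"] >= 7.0,
    # reintegration is a cohort-construction concern: the caller passes the
    # cohort that still contains hormone-user pairs and this filter keeps all
    "include_hormone_users": lambda pairs: pd.Series(True, index=pairs.index),
}


@dataclass
class SensitivitySpec:
    """A named pair filter plus optional extra unpenalized covariates."""

    filter: str = "none"
    extra_covariates: list = field(default_factory=list)
    reuse_support: bool = True

    def __post_init__(self) -> None:
        if self.filter not in _FILTERS:
            raise ValueError(f"unknown filter {self.filter!r}; known: {sorted(_FILTERS)}")


def covariate_differences(
    cohort: PairedCohort, covariates: list
) -> pd.DataFrame:
    """Case-minus-control differences of covariates (one-hot for categoricals)."""
    cols = {}
    for cov in covariates:
        s = cohort.samples[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=cov, drop_first=True).astype(float)
            for c in dummies.columns:
                diff = (
                    dummies.loc[cohort.pairs["case_id"], c].values
                    - dummies.loc[cohort.pairs["control_id"], c].values
                )
                cols[(c, "covariate")] = diff
        else:
            diff = (
                s.loc[cohort.pairs["case_id"]].astype(float).values
                - s.loc[cohort.pairs["control_id"]].astype(float).values
            )
            cols[(cov, "covariate")] = diff
    out = pd.DataFrame(cols, index=cohort.pairs.index)
    if len(cols):
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["feature", "level"])
    return out


def sensitivity_refit(
    spec: SensitivitySpec,
    support: list,
    cohort: PairedCohort,
    features: pd.DataFrame,
    alpha: float = 0.05,
) -> RefitResult:
    """Re-run the unpenalized refit on a filtered/augmented pair set.

    The support is held fixed (``reuse_support``); extra covariates enter
    as unpenalized difference terms.  Types emptied by the filter lose
    their deviation terms with a warning.
    """
    keep = _FILTERS[spec.filter](cohort.pairs)
    sub = cohort.subset(cohort.pairs.index[keep])
    design = PairDiffDesign(
        D=pd.DataFrame(
            features.loc[sub.pairs["case_id"]].values
            - features.loc[sub.pairs["control_id"]].values,
            index=sub.pairs.index,
            columns=features.columns,
        ),
        type_of_pair=sub.pairs["cancer_type"].copy(),
    )
    alive = set(design.types)
    kept_support = []
    for f, lvl in support:
        if lvl != OVERALL and lvl not in alive:
            warnings.warn(f"filter {spec.filter!r} emptied type {lvl!r}; dropping ({f}, {lvl})")
            continue
        kept_support.append((f, lvl))
    X = reduced_design(kept_support, design) if kept_support else None
    extra = covariate_differences(sub, spec.extra_covariates)
    if X is None and extra.empty:
        return refit_unpenalized([], design, alpha=alpha)
    X_full = pd.concat([x for x in (X, extra if not extra.empty else None) if x is not None], axis=1)
    fit = fit_clogit(X_full.values)
    return RefitResult(
        table=_fit_to_table(fit, list(X_full.columns), alpha),
        loglik=fit.loglik,
        n_pairs=fit.n_pairs,
    )


# --------------------------------------------------------------------------
# univariate comparison track
# --------------------------------------------------------------------------


def univariate_clogit(
    features: pd.DataFrame,
    cohort: PairedCohort,
    bmi_adjust: str = "residualize",
    alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Non-mutually-adjusted per-metabolite conditional logistic fits.

    One single-feature fit per (feature, cancer type) plus a pooled
    all-types fit per feature, BMI-adjusted either by residualizing the
    features (default, consistent with the multivariate track) or by
    entering the within-pair BMI difference as a covariate.  q-values are
    Benjamini-Hochberg within each cancer type (and within the pooled
    track).
    """
    from statsmodels.stats.multitest import multipletests

    if bmi_adjust not in ("residualize", "covariate"):
        raise ValueError("bmi_adjust must be 'residualize' or 'covariate'")
    feats = features.loc[cohort.sample_ids]
    if bmi_adjust == "residualize":
        feats = residualize_on_bmi(feats, cohort)
    case, ctrl = cohort.pairs["case_id"], cohort.pairs["control_id"]
    D = feats.loc[case].values - feats.loc[ctrl].values
    bmi_diff = (
        cohort.samples.loc[case, "bmi"].astype(float).values
        - cohort.samples.loc[ctrl, "bmi"].astype(float).values
    )
    types = list(pd.unique(cohort.pairs["cancer_type"]))
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for scope in types + ["pooled"]:
        mask = (
            np.ones(len(D), dtype=bool)
            if scope == "pooled"
            else (cohort.pairs["cancer_type"] == scope).values
        )
        for j, f in enumerate(feats.columns):
            cols = [D[mask, j]]
            if bmi_adjust == "covariate":
                cols.append(bmi_diff[mask])
            fit = fit_clogit(np.column_stack(cols))
            est, se = fit.params[0], fit.se[0]
            ok = bool(fit.estimable[0]) and np.std(D[mask, j]) > 0
            rows.append(
                {
                    "feature": f,
                    "cancer_type": scope,
                    "log_or": est if ok else np.nan,
                    "se": se if ok else np.nan,
                    "ci_low": est - z * se if ok else np.nan,
                    "ci_high": est + z * se if ok else np.nan,
                    "pvalue": fit.wald_pvalues()[0] if ok else np.nan,
                    "estimable": ok,
                }
            )
    out = pd.DataFrame(rows)
    out["qvalue"] = np.nan
    for scope, grp in out.groupby("cancer_type"):
        mask = grp["pvalue"].notna()
        if mask.any():
            q = multipletests(grp.loc[mask, "pvalue"], method=fdr_method)[1]
            out.loc[grp.index[mask], "qvalue"] = q
    return out
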