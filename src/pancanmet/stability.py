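"""Bootstrap stability selection for the data-shared lasso.

The data-shared lasso (including its cross-validated lambda) is re-run on
B bootstrap samples of matched pairs; per term the report tabulates the
proportion of replicates in which it was selected and the average of its
penalized log-OR over those replicates.  Terms of the main-run support
replicated in more than 50% of replicates count as robust; terms outside
the main support selected in more than 55% are reported as additional
candidates (both thresholds strict and configurable).

The resampling unit is the matched pair (this preserves the conditional
likelihood's exchangeability), by default stratified by cancer type so
every replicate keeps the per-type sample sizes.  Replicates draw from
pairs sorted by pair id, so the report is invariant to the ordering of
the input cohort; a master seed spawns one child stream per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _solver
from .containers import PairedCohort
from .dslasso import (
    SUPPORT_TOL,
    PairDiffDesign,
    build_datashared_design,
    cross_validate_lambda,
)


@dataclass
class StabilityReport:
    """Per-term bootstrap selection proportions and average log-ORs."""

    selection_counts: pd.Series  # (feature, level) -> replicates selected
    coef_sums: pd.Series  # sum of coefficients over selecting replicates
    B: int  # requested replicates
    B_effective: int  # successful replicates (denominator)
    seed: int
    stratified: bool
    failures: list

    @property
    def proportions(self) -> pd.Series:
        return self.selection_counts / self.B_effective

    @property
    def average_log_or(self) -> pd.Series:
        """Average penalized log-OR across replicates in which the term was
        selected (NaN for never-selected terms)."""
        with np.errstate(invalid="ignore"):
            return self.coef_sums / self.selection_counts.replace(0, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_selected": self.selection_counts,
                "proportion": self.proportions,
                "avg_log_or": self.average_log_or,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        tab = self.to_frame().reset_index()
        tab.to_csv(path, sep="\t", index=False)


def _stratified_draw(
    pairs: pd.DataFrame, rng: np.random.Generator, stratified: bool
) -> pd.Index:
    """Bootstrap pair ids; drawing from id-sorted pairs within each type
    makes the replicate independent of input row order."""
    if stratified:
        chosen = []
        for t in sorted(pairs["cancer_type"].unique()):
            ids = np.sort(pairs.index[pairs["cancer_type"] == t].values)
            chosen.append(ids[rng.integers(0, len(ids), len(ids))])
        return pd.Index(np.concatenate(chosen))
    ids = np.sort(pairs.index.values)
    return pd.Index(ids[rng.integers(0, len(ids), len(ids))])


def bootstrap_select(
    features: pd.DataFrame,
    cohort: PairedCohort,
    B: int = 100,
    seed: int = 0,
    stratify_by_type: bool = True,
    penalty_mode: str = "sqrt_nk",
    residualize_bmi: bool = True,
    standardize: bool = True,
    types: list | None = None,
    cv_folds: int = 10,
    cv_rule: str = "1se",
    n_lambdas: int = 30,
    min_ratio: float = 0.03,
) -> StabilityReport:
    """Re-run the full selection pipeline on B bootstrap replicates.

    Each replicate resamples matched pairs with replacement (stratified by
    cancer type by default), re-residualizes the features on BMI within
    the replicate, re-standardizes on the replicate's controls, re-selects
    lambda by pair-stratified CV with fresh folds from the replicate's RNG
    stream, and records the data-shared lasso support and coefficients.
    Failed replicates are recorded and excluded from the denominator.
    """
    types = sorted(cohort.types) if types is None else list(types)
    feats = features.columns
    terms = pd.MultiIndex.from_tuples(
        [(f, "overall") for f in feats] + [(f, t) for t in types for f in feats],
        names=["feature", "level"],
    )
    counts = pd.Series(0, index=terms, dtype=float)
    sums = pd.Series(0.0, index=terms)
    failures: list = []

    pairs = cohort.pairs
    case_feat = features.loc[pairs["case_id"]].set_axis(pairs.index)
    ctrl_feat = features.loc[pairs["control_id"]].set_axis(pairs.index)
    bmi_case = cohort.samples.loc[pairs["case_id"], "bmi"].astype(float).set_axis(pairs.index)
    bmi_ctrl = cohort.samples.loc[pairs["control_id"], "bmi"].astype(float).set_axis(pairs.index)

    streams = np.random.SeedSequence(seed).spawn(B)
    done = 0
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        idx = _stratified_draw(pairs, rng, stratify_by_type)
        try:
            Fc = case_feat.loc[idx].values
            Fk = ctrl_feat.loc[idx].values
            if residualize_bmi:
                bc = bmi_case.loc[idx].values
                bk = bmi_ctrl.loc[idx].values
                allb = np.concatenate([bc, bk])
                allf = np.vstack([Fc, Fk])
                X = np.column_stack([np.ones_like(allb), allb])
                coef, *_ = np.linalg.lstsq(X, allf, rcond=None)
                Fc = Fc - np.column_stack([np.ones_like(bc), bc]) @ coef
                Fk = Fk - np.column_stack([np.ones_like(bk), bk]) @ coef
            if standardize:
                sd = Fk.std(axis=0, ddof=1)
                if np.any(sd == 0):
                    raise ValueError("zero control variance in replicate")
                Fc = Fc / sd
                Fk = Fk / sd
            D = pd.DataFrame(Fc - Fk, columns=feats)
            tof = pd.Series(pairs.loc[idx, "cancer_type"].values, index=D.index)
            design = build_datashared_design(
                PairDiffDesign(D=D, type_of_pair=tof), types=types, penalty_mode=penalty_mode
            )
            Z = np.ascontiguousarray(design.Z.values)
            pf = design.penalty_factors.values
            cv = cross_validate_lambda(
                Z, pf, tof, folds=cv_folds, seed=rng,
                n_lambdas=n_lambdas, min_ratio=min_ratio, kkt_tol=1e-7,
            )
            lam = cv.selected(cv_rule)
            lmax = _solver.lambda_max(Z, pf)
            beta0 = None
            if lam < lmax:
                pre = np.geomspace(lmax, lam, 6)[:-1]
                beta0 = _solver.fit_path(Z, pre, pf, kkt_tol=1e-6)[-1]
            beta, _ = _solver.fit_penalized(Z, lam, pf, beta0=beta0, kkt_tol=1e-7)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
            failures.append({"replicate": b, "error": str(exc)})
            continue
        sel = pd.Series(beta, index=design.Z.columns)
        nz = sel[sel.abs() > SUPPORT_TOL]
        counts.loc[nz.index] += 1
        sums.loc[nz.index] += nz
        done += 1

    if done == 0:
        raise RuntimeError("all bootstrap replicates failed")
    return StabilityReport(
        selection_counts=counts,
        coef_sums=sums,
        B=B,
        B_effective=done,
        seed=seed,
        stratified=stratify_by_type,
        failures=failures,
    )


def apply_reporting_thresholds(
    report: StabilityReport,
    main_support: list,
    replicate_threshold: float = 0.50,
    discovery_threshold: float = 0.55,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split terms into replicated main-run associations and new candidates.

    List 1: main-run support terms selected in strictly more than
    ``replicate_threshold`` of replicates.  List 2: terms outside the main
    support selected in strictly more than ``discovery_threshold``,
    reported with their average log-OR.
    """
    tab = report.to_frame()
    main = set(tuple(t) for t in main_support)
    in_main = tab.index.map(lambda t: t in main)
    replicated = tab[in_main & (tab["proportion"] > replicate_threshold)].copy()
    discoveries = tab[~in_main & (tab["proportion"] > discovery_threshold)].copy()
    return (
        replicated.sort_values("proportion", ascending=False),
        discoveries.sort_values("proportion", ascending=False),
    )
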