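"""Pre-processing of targeted metabolomics matrices.

Fixed pipeline order, enforced by :func:`run_preprocess`:

1. metabolite filter  — drop metabolites with more than 25% missing cells
   in at least one study (strict inequality);
2. sample filter      — drop samples with more than 25% missing cells over
   the retained metabolites, together with their pair partners;
3. PCA outlier removal — within each study, robust Mahalanobis distance on
   the leading principal components against a chi-square cutoff;
4. limit imputation   — below-LOD -> LOD/2, below-LLOQ -> LLOQ/2,
   above-ULOQ -> ULOQ, with a study-median fallback when the batch limit is
   unknown;
5. batch-median imputation of the remaining missing cells;
6. natural log transform.

"Missing" for the two 25% filters means status ``missing`` only: censored
cells (below-LOD/LLOQ, above-ULOQ) are imputed by rule in step 4 and are
therefore counted as observed by the filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ABOVE_ULOQ,
    BELOW_LLOQ,
    BELOW_LOD,
    MISSING,
    OBSERVED,
    MetaboliteMatrix,
    PairedCohort,
)


@dataclass
class PreprocessReport:
    """Accounting of exclusions and imputations."""

    excluded_metabolites: dict = field(default_factory=dict)  # name -> reason
    excluded_samples: dict = field(default_factory=dict)  # sample -> reason
    imputation_counts: dict = field(default_factory=dict)  # rule -> count
    per_metabolite_imputations: dict = field(default_factory=dict)  # metab -> {rule: n}
    log: list = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.log.append(msg)

    def count_imputation(self, metabolite: str, rule: str, n: int = 1) -> None:
        self.imputation_counts[rule] = self.imputation_counts.get(rule, 0) + n
        d = self.per_metabolite_imputations.setdefault(metabolite, {})
        d[rule] = d.get(rule, 0) + n

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        self.excluded_metabolites.update(other.excluded_metabolites)
        self.excluded_samples.update(other.excluded_samples)
        for rule, n in other.imputation_counts.items():
            self.imputation_counts[rule] = self.imputation_counts.get(rule, 0) + n
        for m, d in other.per_metabolite_imputations.items():
            mine = self.per_metabolite_imputations.setdefault(m, {})
            for rule, n in d.items():
                mine[rule] = mine.get(rule, 0) + n
        self.log.extend(other.log)
        return self

    def to_dict(self) -> dict:
        return {
            "excluded_metabolites": self.excluded_metabolites,
            "excluded_samples": self.excluded_samples,
            "imputation_counts": self.imputation_counts,
            "per_metabolite_imputations": self.per_metabolite_imputations,
            "log": self.log,
        }

    def __str__(self) -> str:
        lines = [
            f"excluded metabolites: {len(self.excluded_metabolites)}",
            f"excluded samples: {len(self.excluded_samples)}",
            "imputations: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.imputation_counts.items())),
        ]
        lines += [f"  {msg}" for msg in self.log]
        return "\n".join(lines)


def filter_metabolites(
    m: MetaboliteMatrix, threshold: float = 0.25
) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Drop metabolites with missing fraction strictly above ``threshold``
    in at least one study."""
    if m.values.empty:
        raise ValueError("empty metabolite matrix")
    report = PreprocessReport()
    study = m.sample_meta.loc[m.samples, "study"]
    if (study.value_counts() == 0).any():
        raise ValueError("study with zero samples")
    is_missing = m.status == MISSING
    frac = is_missing.groupby(study.values).mean()  # studies x metabolites
    drop = frac.columns[(frac > threshold).any(axis=0)]
    for metab in drop:
        worst = frac[metab].idxmax()
        report.excluded_metabolites[metab] = (
            f"missing fraction {frac.loc[worst, metab]:.1%} > {threshold:.0%} in study {worst}"
        )
    keep = [c for c in m.metabolites if c not in set(drop)]
    report.note(f"metabolite filter: dropped {len(drop)} of {m.shape[1]} metabolites")
    return m.subset(metabolites=keep), report


def filter_samples(
    m: MetaboliteMatrix,
    threshold: float = 0.25,
    cohort: PairedCohort | None = None,
):
    """Drop samples with missing fraction strictly above ``threshold`` over
    the retained metabolites; their pair partners are dropped with them.

    Returns ``(matrix, report)``, or ``(matrix, cohort, report)`` when a
    cohort is supplied (the cohort is subset consistently).
    """
    report = PreprocessReport()
    frac = (m.status == MISSING).mean(axis=1)
    flagged = set(frac.index[frac > threshold])
    for s in flagged:
        report.excluded_samples[s] = f"missing fraction {frac[s]:.1%} > {threshold:.0%}"
    dropped = set(flagged)
    kept_pairs = None
    if cohort is not None:
        partner = {}
        for _, row in cohort.pairs.iterrows():
            partner[row["case_id"]] = row["control_id"]
            partner[row["control_id"]] = row["case_id"]
        for s in flagged:
            mate = partner.get(s)
            if mate is not None and mate not in dropped:
                dropped.add(mate)
                report.excluded_samples[mate] = f"pair partner of excluded sample {s}"
        keep_mask = ~(
            cohort.pairs["case_id"].isin(dropped) | cohort.pairs["control_id"].isin(dropped)
        )
        kept_pairs = cohort.pairs.index[keep_mask]
    keep = [s for s in m.samples if s not in dropped]
    report.note(f"sample filter: dropped {len(dropped)} of {m.shape[0]} samples")
    out = m.subset(samples=keep)
    if cohort is not None:
        return out, cohort.subset(kept_pairs), report
    return out, report


def detect_outliers_pca(
    m: MetaboliteMatrix,
    per_study: bool = True,
    var_explained: float = 0.95,
    chi2_quantile: float = 0.999,
    cohort: PairedCohort | None = None,
) -> set:
    """Flag multivariate outlier samples with a PCA-based rule.

    Within each study: log concentrations (the chi-square reference
    presumes roughly symmetric marginals, which raw concentrations are
    not), robust per-metabolite centring/scaling (median and MAD), PCA on
    the correlation scale, retention of the leading components covering
    ``var_explained`` of the variance, and flagging of samples whose
    Mahalanobis distance in the retained component space exceeds the
    chi-square ``chi2_quantile`` quantile at that dimensionality.  When a
    cohort is supplied, pair partners of flagged samples are included in
    the returned exclusion set.
    """
    flagged: set = set()
    studies = (
        m.sample_meta.loc[m.samples, "study"].unique() if per_study else np.array(["__all__"])
    )
    for st in studies:
        if per_study:
            rows = m.samples[(m.sample_meta.loc[m.samples, "study"] == st).values]
        else:
            rows = m.samples
        X = m.values.loc[rows].where(m.status.loc[rows] == OBSERVED)
        if not m.log_scale:
            X = np.log(X)
        # median-completed values: the rule runs before any imputation
        X = X.fillna(X.median())
        X = X.dropna(axis=1)  # metabolites fully unobserved in this study
        med = X.median()
        mad = (X - med).abs().median() * 1.4826
        scale = mad.where(mad > 0, X.std(ddof=1)).replace(0.0, 1.0)
        Zs = ((X - med) / scale).values
        n, p = Zs.shape
        if n < 3 or p == 0:
            warnings.warn(f"study {st}: too few samples for PCA outlier detection, skipped")
            continue
        Zc = Zs - Zs.mean(axis=0)
        U, S, _ = np.linalg.svd(Zc, full_matrices=False)
        var = S**2 / max(n - 1, 1)
        total = var.sum()
        k = int(np.searchsorted(np.cumsum(var) / total, var_explained) + 1)
        k = min(k, len(var))
        if n <= k:
            warnings.warn(
                f"study {st}: {n} samples < {k} retained components, outlier step skipped"
            )
            continue
        scores = U[:, :k] * S[:k]
        with np.errstate(divide="ignore"):
            d2 = (scores**2 / var[:k]).sum(axis=1)
        cutoff = stats.chi2.ppf(chi2_quantile, df=k)
        flagged.update(np.asarray(rows)[d2 > cutoff])
    if cohort is not None and flagged:
        partner = {}
        for _, row in cohort.pairs.iterrows():
            partner[row["case_id"]] = row["control_id"]
            partner[row["control_id"]] = row["case_id"]
        flagged |= {partner[s] for s in list(flagged) if s in partner}
    return flagged


def _study_median_limit(limits: pd.DataFrame, batch_study: pd.Series, metabolite: str,
                        study: str, kind: str) -> float:
    sub = limits[(limits["metabolite"] == metabolite) & limits[kind].notna()]
    if "study" in limits.columns:
        # limits may cover batches whose samples were excluded upstream
        sub = sub[sub["study"] == study]
    else:
        sub = sub[sub["batch"].map(batch_study) == study]
    if sub.empty:
        return np.nan
    return float(sub[kind].median())


def impute_limits(m: MetaboliteMatrix) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Impute censored cells from quantification limits.

    below-LOD -> LOD/2; below-LLOQ -> LLOQ/2; above-ULOQ -> ULOQ.  When the
    batch-specific limit is unknown, the study-specific median of the known
    batch limits for that metabolite is used instead.
    """
    out = m.copy()
    report = PreprocessReport()
    batch_of = m.sample_meta.loc[m.samples, "batch"]
    batch_study = m.sample_meta.drop_duplicates("batch").set_index("batch")["study"]
    rules = (
        (BELOW_LOD, "lod", 0.5, "lod_half"),
        (BELOW_LLOQ, "lloq", 0.5, "lloq_half"),
        (ABOVE_ULOQ, "uloq", 1.0, "uloq"),
    )
    for status_code, kind, factor, rule_name in rules:
        lut = m.limit_lookup(kind)
        for metab in m.metabolites:
            col_status = out.status[metab]
            idx = col_status.index[col_status == status_code]
            if idx.empty:
                continue
            for s in idx:
                b = batch_of[s]
                key = (b, metab)
                lim = lut.get(key, np.nan)
                if np.isnan(lim):
                    lim = _study_median_limit(m.limits, batch_study, metab, batch_study[b], kind)
                    if np.isnan(lim):
                        raise ValueError(
                            f"no {kind.upper()} recoverable for metabolite {metab!r} "
                            f"in batch {b!r} or its study"
                        )
                out.values.at[s, metab] = lim * factor
                out.status.at[s, metab] = OBSERVED
            report.count_imputation(metab, rule_name, len(idx))
    report.note(
        "limit imputation: " + ", ".join(f"{k}={v}" for k, v in report.imputation_counts.items())
    )
    return out, report


def impute_batch_median(m: MetaboliteMatrix) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Impute remaining missing cells to the batch-specific median of the
    non-missing measurements (study median fallback for all-missing batches)."""
    out = m.copy()
    report = PreprocessReport()
    batch = m.sample_meta.loc[m.samples, "batch"].values
    study = m.sample_meta.loc[m.samples, "study"].values
    vals = out.values
    miss = out.status == MISSING
    if not miss.values.any():
        return out, report
    batch_median = vals.groupby(batch).transform("median")
    study_median = vals.groupby(study).transform("median")
    for metab in m.metabolites:
        col_miss = miss[metab]
        if not col_miss.any():
            continue
        fill = batch_median.loc[col_miss, metab]
        nan_fill = fill.isna()
        if nan_fill.any():
            warnings.warn(
                f"metabolite {metab!r}: batch(es) with no non-missing values, "
                "falling back to study median"
            )
            fill = fill.where(~nan_fill, study_median.loc[col_miss, metab])
        vals.loc[col_miss, metab] = fill
        out.status.loc[col_miss, metab] = OBSERVED
        report.count_imputation(metab, "batch_median", int(col_miss.sum()))
    report.note(
        f"batch-median imputation: {report.imputation_counts.get('batch_median', 0)} cells"
    )
    return out, report


def log_transform(m: MetaboliteMatrix, base: float = np.e) -> MetaboliteMatrix:
    """Elementwise logarithm (natural by default) of all concentrations."""
    if m.log_scale:
        raise ValueError("matrix is already on the log scale")
    vals = m.values.values
    bad = ~(vals > 0) & np.isfinite(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"nonpositive value at sample {m.samples[i]!r}, metabolite {m.metabolites[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        logged = np.log(vals)
        if base != np.e:
            logged = logged / np.log(base)
    return MetaboliteMatrix(
        pd.DataFrame(logged, index=m.samples, columns=m.metabolites),
        m.status.copy(),
        m.metabolite_meta.copy(),
        m.limits.copy(),
        m.sample_meta.copy(),
        log_scale=True,
    )


def run_preprocess(
    m: MetaboliteMatrix,
    cohort: PairedCohort,
    missing_threshold: float = 0.25,
    outlier_var_explained: float = 0.95,
    outlier_chi2_quantile: float = 0.999,
    log_base: float = np.e,
) -> tuple[pd.DataFrame, PairedCohort, PreprocessReport]:
    """Run the full fixed-order pre-processing pipeline.

    Returns the log-scale samples x metabolites feature table (plain
    DataFrame: every cell observed), the consistently filtered cohort, and
    the accumulated report.
    """
    report = PreprocessReport()
    report.note(f"input: {m.shape[0]} samples x {m.shape[1]} metabolites")

    m, rep = filter_metabolites(m, threshold=missing_threshold)
    report.merge(rep)

    m, cohort, rep = filter_samples(m, threshold=missing_threshold, cohort=cohort)
    report.merge(rep)

    flagged = detect_outliers_pca(
        m,
        per_study=True,
        var_explained=outlier_var_explained,
        chi2_quantile=outlier_chi2_quantile,
        cohort=cohort,
    )
    if flagged:
        for s in flagged:
            report.excluded_samples.setdefault(s, "PCA outlier (or partner)")
        keep_pairs = cohort.pairs.index[
            ~(
                cohort.pairs["case_id"].isin(flagged)
                | cohort.pairs["control_id"].isin(flagged)
            )
        ]
        cohort = cohort.subset(keep_pairs)
        m = m.subset(samples=[s for s in m.samples if s not in flagged])
    report.note(f"outlier removal: {len(flagged)} samples flagged")

    m, rep = impute_limits(m)
    report.merge(rep)
    m, rep = impute_batch_median(m)
    report.merge(rep)

    if (m.status != OBSERVED).values.any():
        raise RuntimeError("cells left unimputed after the imputation steps")

    m = log_transform(m, base=log_base)
    features = m.values
    # keep only samples that still belong to a complete pair
    features = features.loc[cohort.sample_ids.sort_values()]
    report.note(
        f"output: {features.shape[0]} samples x {features.shape[1]} metabolites (log scale)"
    )
    return features, cohort, report
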