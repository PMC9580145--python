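"""End-to-end orchestration: cohort assembly, analysis variants, reports.

``assemble_cohort`` applies the cohort-level exclusion cascade (small
batches, unmatched samples, cancer-subtype restriction, hormone users) and
logs per-step counts.  ``run_main`` executes the full analysis —
preprocessing, variable clustering, BMI residualization, data-shared lasso
with CV lambda, post-selection refits and secondary analyses, bootstrap
stability — and writes every table as TSV/JSON together with a manifest
whose stage-by-stage counts reconcile.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import postfit, stability, synth
from .containers import MetaboliteMatrix, PairedCohort
from .dslasso import OVERALL, DataSharedLasso
from .preprocess import run_preprocess
from .varclust import cluster_heatmap_table, fit_varclust, score_representatives

VARIANTS = ("main", "extended_metabolites", "prostate_all_pairs")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (defaults = headline analysis)."""

    variant: str = "main"
    analysis_types: list = field(
        default_factory=lambda: list(synth.STUDY_PAIR_COUNTS)
    )
    unknown_stage_type: str = "UnkPrC"  # retained only by prostate_all_pairs
    p150_study: str = "crc_2"  # dropped by extended_metabolites
    extended_metabolites: list = field(default_factory=list)
    missing_threshold: float = 0.25
    cluster_min_explained: float = 0.80
    outlier_chi2_quantile: float = 0.999
    outlier_var_explained: float = 0.95
    exclude_hormone_users: bool = True
    exclude_small_batches: bool = True
    small_batch_min: int = 10
    penalty_mode: str = "sqrt_nk"
    cv_folds: int = 10
    cv_rule: str = "1se"
    n_lambdas: int = 30
    lambda_min_ratio: float = 0.03
    bootstrap_B: int = 100
    replication_threshold: float = 0.50
    discovery_threshold: float = 0.55
    followup_exclusions: list = field(default_factory=lambda: [2.0, 7.0])
    sensitivity_covariates: list = field(
        default_factory=lambda: ["education", "waist", "height", "physical_activity",
                                 "smoking", "alcohol", "nsaid_use"]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        for name, lo, hi in (
            ("missing_threshold", 0, 1),
            ("cluster_min_explained", 0, 1),
            ("replication_threshold", 0, 1),
            ("discovery_threshold", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def types_for_variant(self) -> list:
        types = list(self.analysis_types)
        if self.variant == "prostate_all_pairs" and self.unknown_stage_type not in types:
            types.append(self.unknown_stage_type)
        return types

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def assemble_cohort(
    matrix: MetaboliteMatrix, cohort: PairedCohort, config: RunConfig
) -> tuple[MetaboliteMatrix, PairedCohort, dict]:
    """Apply the cohort exclusion cascade; returns per-step counts.

    Order: study subset (variant) -> small-batch exclusion -> unmatched
    removal -> cancer-subtype restriction (non-analysis types such as
    other liver cancers; unknown-stage prostate unless the variant keeps
    it) -> hormone-user pair exclusion.
    """
    counts = {"pairs_in": cohort.n_pairs}
    pairs = cohort.pairs

    if config.variant == "extended_metabolites":
        keep = pairs["study"] != config.p150_study
        counts["excluded_p150_study_pairs"] = int((~keep).sum())
        pairs = pairs[keep]

    if config.exclude_small_batches:
        batch_sizes = matrix.sample_meta["batch"].value_counts()
        small = set(batch_sizes.index[batch_sizes < config.small_batch_min])
        keep = ~pairs["batch"].isin(small)
        counts["excluded_small_batch_pairs"] = int((~keep).sum())
        pairs = pairs[keep]

    have = set(matrix.samples)
    keep = pairs["case_id"].isin(have) & pairs["control_id"].isin(have)
    counts["excluded_unmatched_pairs"] = int((~keep).sum())
    pairs = pairs[keep]

    allowed = set(config.types_for_variant())
    keep = pairs["cancer_type"].isin(allowed)
    counts["excluded_non_analysis_type_pairs"] = int((~keep).sum())
    pairs = pairs[keep]

    if config.exclude_hormone_users:
        hu = cohort.samples["hormone_use"].astype(bool) if "hormone_use" in cohort.samples else None
        if hu is not None:
            keep = ~(hu.loc[pairs["case_id"]].values | hu.loc[pairs["control_id"]].values)
            counts["excluded_hormone_user_pairs"] = int((~keep).sum())
            pairs = pairs[keep]

    out = cohort.subset(pairs.index)
    counts["pairs_analyzed"] = out.n_pairs
    excl = sum(v for k, v in counts.items() if k.startswith("excluded_"))
    assert counts["pairs_in"] - excl == counts["pairs_analyzed"]
    matrix = matrix.subset(samples=[s for s in matrix.samples if s in set(out.sample_ids)])
    return matrix, out, counts


def _truth_scores(results, truth: synth.TruthRecord, cluster_model) -> dict:
    """Truth-aware end-to-end scoring of the overall-term selection."""
    assign = cluster_model.assignment
    true_feats = {
        assign[m]
        for m, v in truth.mu_true.items()
        if v != 0 and m in assign
    }
    selected = {f for f, lvl in results.support if lvl == OVERALL}
    tp = len(selected & true_feats)
    sens = tp / len(true_feats) if true_feats else np.nan
    fdp = (len(selected) - tp) / len(selected) if selected else 0.0
    return {
        "true_overall_features": sorted(true_feats),
        "selected_overall_features": sorted(selected),
        "selection_sensitivity": sens,
        "false_discovery_proportion": fdp,
    }


def run_main(
    config: RunConfig,
    matrix: MetaboliteMatrix,
    cohort: PairedCohort,
    truth: synth.TruthRecord | None = None,
    outdir: str | Path | None = None,
    bootstrap_B: int | None = None,
) -> dict:
    """Execute the full pipeline; returns (and optionally writes) a bundle."""
    t_start = time.time()
    stages: dict = {}
    manifest: dict = {"config": asdict(config), "seed": config.seed}

    def clock(name):
        stages[name] = time.time()

    clock("assemble")
    matrix, cohort, counts = assemble_cohort(matrix, cohort, config)
    manifest["cohort_counts"] = counts

    clock("preprocess")
    features_log, cohort, prep_report = run_preprocess(
        matrix,
        cohort,
        missing_threshold=config.missing_threshold,
        outlier_var_explained=config.outlier_var_explained,
        outlier_chi2_quantile=config.outlier_chi2_quantile,
    )
    manifest["preprocess"] = {
        "n_samples": features_log.shape[0],
        "n_metabolites": features_log.shape[1],
        "excluded_metabolites": len(prep_report.excluded_metabolites),
        "excluded_samples": len(prep_report.excluded_samples),
    }

    clock("cluster")
    cluster_model = fit_varclust(
        features_log, cohort.control_ids, min_explained=config.cluster_min_explained
    )
    scored = score_representatives(features_log, cluster_model)
    manifest["clustering"] = {
        "n_features": len(cluster_model.features),
        "n_clusters": cluster_model.n_clusters(),
        "n_isolated": cluster_model.n_isolated(),
        "mean_explained_share": float(np.mean(list(cluster_model.explained_share.values()))),
    }

    clock("fit")
    model = DataSharedLasso(
        scored, cohort, penalty_mode=config.penalty_mode,
        types=sorted(set(cohort.types)),
    )
    results = model.fit(
        cv_folds=config.cv_folds,
        cv_rule=config.cv_rule,
        seed=config.seed,
        n_lambdas=config.n_lambdas,
        min_ratio=config.lambda_min_ratio,
    )
    manifest["fit"] = {
        "lambda": results.lambda_,
        "n_selected": len(results.support),
        "kkt": results.diagnostics["kkt"],
    }

    clock("postfit")
    refit = results.refit_unpenalized()
    extended = postfit.extended_typespecific_comparison(results.support, model.pair_design)
    support_feats = sorted({f for f, _ in results.support})
    secondary_rows = []
    for f in support_feats:
        rec = {"feature": f}
        try:
            rec["linearity_pvalue"] = postfit.spline_linearity_test(
                model.features[f], cohort
            )["pvalue"]
        except ValueError as exc:
            warnings.warn(f"linearity test skipped for {f}: {exc}")
            rec["linearity_pvalue"] = np.nan
        try:
            rec["bmi_interaction_pvalue"] = postfit.bmi_effect_modification(
                model.features[f], cohort
            )["pvalue"]
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"BMI effect modification skipped for {f}: {exc}")
            rec["bmi_interaction_pvalue"] = np.nan
        secondary_rows.append(rec)
    secondary = pd.DataFrame(secondary_rows).set_index("feature") if secondary_rows else pd.DataFrame()

    sensitivities = {}
    for cut in config.followup_exclusions:
        name = f"exclude_followup_lt_{int(cut)}y"
        sensitivities[name] = postfit.sensitivity_refit(
            postfit.SensitivitySpec(filter=name), results.support, cohort, model.features
        )
    covs = [c for c in config.sensitivity_covariates if c in cohort.samples.columns]
    if covs:
        sensitivities["extra_covariates"] = postfit.sensitivity_refit(
            postfit.SensitivitySpec(filter="none", extra_covariates=covs),
            results.support, cohort, model.features,
        )

    univariate = postfit.univariate_clogit(scored, cohort)

    clock("stability")
    B = config.bootstrap_B if bootstrap_B is None else bootstrap_B
    report = stability.bootstrap_select(
        scored,
        cohort,
        B=B,
        seed=config.seed + 1,
        penalty_mode=config.penalty_mode,
        types=sorted(set(cohort.types)),
        cv_folds=config.cv_folds,
        cv_rule=config.cv_rule,
        n_lambdas=config.n_lambdas,
        min_ratio=config.lambda_min_ratio,
    )
    replicated, discoveries = stability.apply_reporting_thresholds(
        report,
        results.support,
        replicate_threshold=config.replication_threshold,
        discovery_threshold=config.discovery_threshold,
    )
    manifest["stability"] = {
        "B": B,
        "B_effective": report.B_effective,
        "n_replicated": len(replicated),
        "n_discoveries": len(discoveries),
    }

    if truth is not None:
        manifest["truth_scores"] = _truth_scores(results, truth, cluster_model)

    prev = None
    manifest["stage_seconds"] = {}
    for name, t0 in list(stages.items()):
        if prev is not None:
            manifest["stage_seconds"][prev[0]] = round(t0 - prev[1], 3)
        prev = (name, t0)
    manifest["stage_seconds"][prev[0]] = round(time.time() - prev[1], 3)
    manifest["total_seconds"] = round(time.time() - t_start, 3)

    bundle = {
        "manifest": manifest,
        "preprocess_report": prep_report,
        "cluster_model": cluster_model,
        "features": scored,
        "cohort": cohort,
        "features_log": features_log,
        "model": model,
        "results": results,
        "refit": refit,
        "extended": extended,
        "secondary": secondary,
        "sensitivities": sensitivities,
        "univariate": univariate,
        "stability": report,
        "replicated": replicated,
        "discoveries": discoveries,
    }
    if outdir is not None:
        render_reports(bundle, outdir)
    return bundle


def render_reports(bundle: dict, outdir: str | Path) -> list:
    """Write every report table of a completed bundle; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def w(path: Path):
        written.append(path)
        return path

    results = bundle["results"]
    # feature x type signed-effect matrix (0 = not selected)
    results.coefficient_table().to_csv(w(outdir / "effect_matrix.tsv"), sep="\t")
    results.to_json(w(outdir / "dsl_fit.json"))
    bundle["cluster_model"].to_json(w(outdir / "cluster_model.json"))
    cluster_heatmap_table(
        bundle["cluster_model"],
        bundle["features_log"].loc[bundle["cohort"].control_ids],
    ).to_csv(w(outdir / "cluster_composition.tsv"), sep="\t", index=False)

    refit = bundle["refit"]
    if not refit.empty:
        refit.table.reset_index().to_csv(w(outdir / "refit_forest.tsv"), sep="\t", index=False)
    if len(bundle["extended"]):
        bundle["extended"].reset_index().to_csv(
            w(outdir / "extended_comparison.tsv"), sep="\t", index=False
        )
    if len(bundle["secondary"]):
        bundle["secondary"].reset_index().to_csv(
            w(outdir / "secondary_checks.tsv"), sep="\t", index=False
        )
    for name, res in bundle["sensitivities"].items():
        if not res.empty:
            res.table.reset_index().to_csv(
                w(outdir / f"sensitivity_{name}.tsv"), sep="\t", index=False
            )
    bundle["univariate"].to_csv(w(outdir / "univariate.tsv"), sep="\t", index=False)
    bundle["stability"].to_tsv(w(outdir / "stability.tsv"))
    bundle["replicated"].reset_index().to_csv(
        w(outdir / "stability_replicated.tsv"), sep="\t", index=False
    )
    bundle["discoveries"].reset_index().to_csv(
        w(outdir / "stability_discoveries.tsv"), sep="\t", index=False
    )
    (outdir / "preprocess_report.json").write_text(
        json.dumps(bundle["preprocess_report"].to_dict(), indent=1, default=str)
    )
    written.append(outdir / "preprocess_report.json")
    (outdir / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=1, default=str)
    )
    written.append(outdir / "manifest.json")
    return written
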