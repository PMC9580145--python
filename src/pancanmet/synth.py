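"""Synthetic matched case-control cohorts with metabolomics-like structure.

The generator emulates the statistical skeleton of a multi-study nested
case-control metabolomics resource: several studies covering a set of cancer
types with 1:1 matched pairs, a metabolite panel with block-correlated
(cluster) structure on the log scale, batch-specific limit-of-detection
left-censoring, missing-at-random cells, BMI confounding (BMI shifts
metabolite levels and cancer risk), additive batch effects, and sparse
log-odds effects decomposed into an overall vector ``mu`` plus per-type
deviation vectors ``delta_k``.

Case status is generated by a mechanism that is exactly compatible with the
conditional likelihood fitted downstream: within each matched pair the case
is the member ``i`` with probability ``exp(eta_i) / (exp(eta_1) +
exp(eta_2))``, where ``eta`` is the linear predictor on the latent
(biological) log scale.  This makes parameter recovery well-posed: the
pair-difference conditional logistic model is the true model.

Small deterministic fixtures for unit tests live in :func:`make_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ABOVE_ULOQ,
    BELOW_LLOQ,
    BELOW_LOD,
    FULLY_QUANTITATIVE,
    MISSING,
    OBSERVED,
    SEMI_QUANTITATIVE,
    MetaboliteMatrix,
    PairedCohort,
)

# chemical classes cycled over clusters; the first two are measured with a
# fully quantitative assay (LLOQ/ULOQ), the rest semi-quantitatively (LOD)
_CHEM_CYCLE = (
    "aminoacid",
    "biogenic_amine",
    "PC",
    "lysoPC",
    "SM",
    "acylcarnitine",
    "hexose",
)
_FULLY_QUANT_CLASSES = {"aminoacid", "biogenic_amine"}

_BMI_REF = 26.0


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_pairs_per_type : dict
        Cancer type label -> number of matched pairs (exact).
    n_metabolites : int
        Size of the metabolite panel.
    cluster_spec : list of (size, rho)
        Block-exchangeable correlation blocks on the latent log scale;
        sizes must sum to at most ``n_metabolites`` (the remainder are
        mutually uncorrelated, "isolated" metabolites).  Each ``rho`` must
        lie in [0, 1) so the implied covariance is positive definite.
    mu_true, delta_true :
        Overall log-OR per metabolite (length p) and per-type deviation
        log-ORs (dict type -> length-p vector; absent types mean zero
        deviations).  Effects are per latent standard deviation.
    bmi_effect_on_metabolite :
        Slope of each metabolite's latent log level on (BMI - 26).
    bmi_log_or : dict
        Per-type log-OR of (BMI - 26) on case status.
    lod_quantile : float
        Fraction of each batch's control distribution censored below the
        limit (LOD for semi-quantitative metabolites, LLOQ for fully
        quantitative ones).  0 disables left-censoring.
    uloq_quantile : float
        Upper quantification limit as a batch control quantile for fully
        quantitative metabolites; 1 disables upper censoring.
    missing_rate : float
        Probability that an uncensored cell is missing at random.
    n_batches_per_study, batch_shift_sd :
        Batch structure; batch effects are additive shifts on the log
        scale, drawn N(0, batch_shift_sd) per (batch, metabolite).
    lod_unknown_rate : float
        Fraction of (batch, metabolite) limit records dropped from the
        limits table, to exercise the study-median LOD fallback.
    study_map : dict
        Cancer type -> study name, or a tuple of study names when a type
        is recruited through several studies (pairs are split evenly).
    sex_of_type : dict
        Cancer type -> fraction of female pairs (sex is a matching factor,
        so it is constant within a pair).
    hormone_use_rate : float
        Baseline exogenous-hormone-use probability among women.
    seed : int
        Master seed; identical config + seed reproduce the cohort bit for
        bit.
    """

    n_pairs_per_type: dict
    n_metabolites: int
    cluster_spec: list = field(default_factory=list)
    mu_true: np.ndarray | None = None
    delta_true: dict = field(default_factory=dict)
    bmi_effect_on_metabolite: np.ndarray | None = None
    bmi_log_or: dict = field(default_factory=dict)
    lod_quantile: float = 0.0
    uloq_quantile: float = 1.0
    missing_rate: float = 0.0
    n_batches_per_study: int = 3
    batch_shift_sd: float = 0.0
    lod_unknown_rate: float = 0.0
    study_map: dict | None = None
    sex_of_type: dict = field(default_factory=dict)
    hormone_use_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.n_metabolites
        if p <= 0:
            raise ValueError("n_metabolites must be positive")
        for t, n in self.n_pairs_per_type.items():
            if n <= 0:
                raise ValueError(f"n_pairs_per_type[{t!r}] must be positive")
        sizes = [s for s, _ in self.cluster_spec]
        if any(s < 1 for s in sizes):
            raise ValueError("cluster sizes must be >= 1")
        if sum(sizes) > p:
            raise ValueError("cluster sizes must sum to at most n_metabolites")
        for s, rho in self.cluster_spec:
            if not (0.0 <= rho < 1.0):
                raise ValueError(
                    f"intra-cluster correlation {rho} outside [0, 1): the implied "
                    "block-exchangeable covariance would not be positive definite"
                )
        for name in ("lod_quantile", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 < self.uloq_quantile <= 1.0):
            raise ValueError("uloq_quantile must be in (0, 1]")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be nonnegative")
        if self.mu_true is None:
            self.mu_true = np.zeros(p)
        self.mu_true = np.asarray(self.mu_true, dtype=float)
        if self.mu_true.shape != (p,):
            raise ValueError("mu_true must have length n_metabolites")
        self.delta_true = {k: np.asarray(v, dtype=float) for k, v in self.delta_true.items()}
        for k, v in self.delta_true.items():
            if v.shape != (p,):
                raise ValueError(f"delta_true[{k!r}] must have length n_metabolites")
        if self.bmi_effect_on_metabolite is None:
            self.bmi_effect_on_metabolite = np.zeros(p)
        self.bmi_effect_on_metabolite = np.asarray(self.bmi_effect_on_metabolite, dtype=float)
        if self.bmi_effect_on_metabolite.shape != (p,):
            raise ValueError("bmi_effect_on_metabolite must have length n_metabolites")

    @property
    def types(self) -> list:
        return list(self.n_pairs_per_type)

    def resolved_study_map(self) -> dict:
        """Type -> tuple of study names (default: one study per type)."""
        out = {}
        user = self.study_map or {}
        for t in self.types:
            studies = user.get(t, f"study_{t}")
            out[t] = (studies,) if isinstance(studies, str) else tuple(studies)
        return out


@dataclass
class TruthRecord:
    """Ground truth of a synthetic cohort, retrievable by seed."""

    mu_true: pd.Series
    delta_true: pd.DataFrame  # types x metabolites
    clusters: dict  # metabolite -> cluster id (-1 = isolated)
    latent: pd.DataFrame  # samples x metabolites, uncensored latent log levels
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "mu_true": self.mu_true.to_dict(),
            "delta_true": {k: row.to_dict() for k, row in self.delta_true.iterrows()},
            "clusters": self.clusters,
            "latent": {
                "index": list(self.latent.index),
                "columns": list(self.latent.columns),
                "data": self.latent.values.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        latent = pd.DataFrame(
            payload["latent"]["data"],
            index=payload["latent"]["index"],
            columns=payload["latent"]["columns"],
        )
        mu = pd.Series(payload["mu_true"])
        delta = pd.DataFrame(payload["delta_true"]).T[mu.index]
        return cls(mu, delta, payload["clusters"], latent, payload["seed"])


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _metabolite_names(config: SynthConfig) -> tuple[list, dict, list]:
    """Deterministic metabolite names, cluster map and chemical classes."""
    p = config.n_metabolites
    clusters: dict = {}
    chem: list = [None] * p
    names: list = [None] * p
    idx = 0
    for c, (size, _rho) in enumerate(config.cluster_spec):
        cls_label = _CHEM_CYCLE[c % len(_CHEM_CYCLE)]
        for _ in range(size):
            names[idx] = f"{cls_label}_{idx:03d}"
            chem[idx] = cls_label
            clusters[names[idx]] = c
            idx += 1
    iso = 0
    while idx < p:
        cls_label = _CHEM_CYCLE[iso % len(_CHEM_CYCLE)]
        names[idx] = f"{cls_label}_{idx:03d}"
        chem[idx] = cls_label
        clusters[names[idx]] = -1
        idx += 1
        iso += 1
    return names, clusters, chem


def _draw_latent(rng: np.random.Generator, n: int, config: SynthConfig) -> np.ndarray:
    """Latent N(0, Sigma) draws with block-exchangeable correlation."""
    p = config.n_metabolites
    X = rng.standard_normal((n, p))
    idx = 0
    for size, rho in config.cluster_spec:
        if rho > 0:
            shared = rng.standard_normal((n, 1))
            X[:, idx : idx + size] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * X[
                :, idx : idx + size
            ]
        idx += size
    return X


def generate_cohort(config: SynthConfig) -> tuple[MetaboliteMatrix, PairedCohort, TruthRecord]:
    """Generate a synthetic matched case-control metabolomics cohort.

    Returns the measurement matrix (with censoring/missing statuses and a
    batch-level limits table), the matched cohort and the ground truth.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_metabolites
    names, cluster_map, chem = _metabolite_names(config)
    study_map = config.resolved_study_map()
    types = config.types
    n_pairs = int(sum(config.n_pairs_per_type.values()))
    n = 2 * n_pairs

    # ---- pair-level design: study, batch, sex, age stratum (shared in pair)
    pair_type = np.concatenate(
        [np.repeat(t, config.n_pairs_per_type[t]) for t in types]
    )
    pair_study = np.empty(n_pairs, dtype=object)
    offset = 0
    for t in types:
        nt = config.n_pairs_per_type[t]
        studies = study_map[t]
        # split pairs evenly (deterministically) over the type's studies
        pair_study[offset : offset + nt] = np.array(studies)[np.arange(nt) % len(studies)]
        offset += nt
    all_studies = sorted(set(pair_study))
    pair_batch = np.array(
        [
            f"{s}_b{rng.integers(1, config.n_batches_per_study + 1):02d}"
            for s in pair_study
        ],
        dtype=object,
    )
    frac_female = np.array([config.sex_of_type.get(t, 0.5) for t in pair_type])
    pair_sex = np.where(rng.random(n_pairs) < frac_female, "F", "M")
    pair_age = rng.normal(57.0, 7.5, n_pairs).round(1)
    follow_up = rng.gamma(shape=4.0, scale=2.1, size=n_pairs).round(2)

    # ---- sample-level draws (member 0 and 1 of each pair)
    bmi = np.exp(rng.normal(np.log(26.5), 0.15, (n_pairs, 2)))
    latent = _draw_latent(rng, n, config).reshape(n_pairs, 2, p)
    bmi_c = bmi - _BMI_REF
    biol = latent + bmi_c[:, :, None] * config.bmi_effect_on_metabolite[None, None, :]

    # ---- case assignment: conditional-logistic-compatible within-pair draw
    coef = np.stack(
        [
            config.mu_true + config.delta_true.get(t, np.zeros(p))
            for t in types
        ]
    )  # K x p
    type_idx = {t: i for i, t in enumerate(types)}
    pair_coef = coef[[type_idx[t] for t in pair_type]]  # n_pairs x p
    bmi_or = np.array([config.bmi_log_or.get(t, 0.0) for t in pair_type])
    eta = np.einsum("ijp,ip->ij", biol, pair_coef) + bmi_or[:, None] * bmi_c
    p_case_first = 1.0 / (1.0 + np.exp(-(eta[:, 0] - eta[:, 1])))
    case_is_first = rng.random(n_pairs) < p_case_first

    # ---- identities
    sample_ids = np.array([f"S{i:06d}" for i in range(n)]).reshape(n_pairs, 2)
    pair_ids = [f"P{i:05d}" for i in range(n_pairs)]
    case_ids = np.where(case_is_first, sample_ids[:, 0], sample_ids[:, 1])
    control_ids = np.where(case_is_first, sample_ids[:, 1], sample_ids[:, 0])

    # ---- measured log concentrations: scale + batch shift + biological level
    log_scale = rng.normal(np.log(30.0), 0.8, p)
    batches = sorted(set(pair_batch))
    shift = {
        b: rng.normal(0.0, config.batch_shift_sd, p) if config.batch_shift_sd > 0 else np.zeros(p)
        for b in batches
    }
    batch_shift = np.stack([shift[b] for b in pair_batch])  # n_pairs x p
    logconc = biol + log_scale[None, None, :] + batch_shift[:, None, :]
    values = np.exp(logconc).reshape(n, p)

    flat_ids = sample_ids.reshape(n)
    flat_batch = np.repeat(pair_batch, 2)
    flat_study = np.repeat(pair_study, 2)
    is_control = np.ones(n, dtype=bool)
    is_control[np.where(case_is_first, np.arange(0, n, 2), np.arange(1, n, 2))] = False

    status = np.full((n, p), OBSERVED, dtype=object)
    quant_class = np.array(
        [FULLY_QUANTITATIVE if c in _FULLY_QUANT_CLASSES else SEMI_QUANTITATIVE for c in chem]
    )

    # ---- batch-specific quantification limits and censoring flags
    limit_rows = []
    semi = quant_class == SEMI_QUANTITATIVE
    study_of_batch = {}
    for b, s in zip(pair_batch, pair_study):
        study_of_batch.setdefault(b, s)
    for b in batches:
        in_b = flat_batch == b
        ctrl_b = in_b & is_control
        if ctrl_b.sum() < 2:
            ctrl_b = in_b  # tiny batch: fall back to all members
        for j in range(p):
            row = {"batch": b, "study": study_of_batch[b], "metabolite": names[j],
                   "lod": np.nan, "lloq": np.nan, "uloq": np.nan}
            if config.lod_quantile > 0:
                lim = float(np.quantile(values[ctrl_b, j], config.lod_quantile))
                below = in_b & (values[:, j] < lim)
                status[below, j] = BELOW_LOD if semi[j] else BELOW_LLOQ
                row["lod" if semi[j] else "lloq"] = lim
            if not semi[j] and config.uloq_quantile < 1.0:
                up = float(np.quantile(values[ctrl_b, j], config.uloq_quantile))
                above = in_b & (values[:, j] > up)
                status[above, j] = ABOVE_ULOQ
                row["uloq"] = up
            if not all(np.isnan(v) for v in (row["lod"], row["lloq"], row["uloq"])):
                limit_rows.append(row)
    limits = pd.DataFrame(
        limit_rows, columns=["batch", "study", "metabolite", "lod", "lloq", "uloq"]
    )

    # optionally hide some batch limits so the study-median fallback is used
    if config.lod_unknown_rate > 0 and len(limits):
        drop = rng.random(len(limits)) < config.lod_unknown_rate
        # never drop the last known limit of a (study, metabolite)
        keep_last = limits.loc[~drop].groupby(["study", "metabolite"]).size()
        for i in np.where(drop)[0]:
            key = (limits.at[i, "study"], limits.at[i, "metabolite"])
            if keep_last.get(key, 0) == 0:
                drop[i] = False
                keep_last[key] = 1
        limits = limits.loc[~drop].reset_index(drop=True)

    # ---- missing completely at random among remaining observed cells
    if config.missing_rate > 0:
        mcar = (rng.random((n, p)) < config.missing_rate) & (status == OBSERVED)
        status[mcar] = MISSING

    vals = values.copy()
    vals[status != OBSERVED] = np.nan

    values_df = pd.DataFrame(vals, index=flat_ids, columns=names)
    status_df = pd.DataFrame(status, index=flat_ids, columns=names)
    metabolite_meta = pd.DataFrame(
        {"quant_class": quant_class, "chem_class": chem}, index=pd.Index(names, name="metabolite")
    )
    sample_meta = pd.DataFrame(
        {"study": flat_study, "batch": flat_batch}, index=pd.Index(flat_ids, name="sample")
    )
    matrix = MetaboliteMatrix(values_df, status_df, metabolite_meta, limits, sample_meta)

    # ---- cohort tables
    sex_rep = np.repeat(pair_sex, 2)
    female = sex_rep == "F"
    samples = pd.DataFrame(
        {
            "bmi": bmi.reshape(n).round(2),
            "sex": sex_rep,
            "age": np.repeat(pair_age, 2),
            "hormone_use": (female & (rng.random(n) < config.hormone_use_rate)).astype(int),
            "education": rng.integers(0, 5, n),
            "waist": (bmi.reshape(n) * 2.8 + rng.normal(15, 6, n)).round(1),
            "height": np.where(female, rng.normal(163, 7, n), rng.normal(176, 7, n)).round(1),
            "physical_activity": rng.integers(0, 4, n),
            "smoking": rng.integers(0, 3, n),
            "alcohol": rng.gamma(1.5, 8.0, n).round(1),
            "nsaid_use": (rng.random(n) < 0.25).astype(int),
            "menopausal_status": np.where(
                female, np.where(np.repeat(pair_age, 2) >= 51, "post", "pre"), "na"
            ),
        },
        index=pd.Index(flat_ids, name="sample"),
    )
    pairs = pd.DataFrame(
        {
            "case_id": case_ids,
            "control_id": control_ids,
            "study": pair_study,
            "cancer_type": pair_type,
            "batch": pair_batch,
            "follow_up_years": follow_up,
        },
        index=pd.Index(pair_ids, name="pair"),
    )
    cohort = PairedCohort(pairs, samples)

    truth = TruthRecord(
        mu_true=pd.Series(config.mu_true, index=names),
        delta_true=pd.DataFrame(
            {t: config.delta_true.get(t, np.zeros(p)) for t in types}, index=names
        ).T,
        clusters=cluster_map,
        latent=pd.DataFrame(latent.reshape(n, p), index=flat_ids, columns=names),
        seed=config.seed,
    )
    return matrix, cohort, truth


# --------------------------------------------------------------------------
# study-scale default configuration
# --------------------------------------------------------------------------

#: matched-pair counts of the eight cancer types in the emulated design
STUDY_PAIR_COUNTS = {
    "BrC": 1088,
    "CRC": 1500,
    "EnC": 689,
    "KiC": 511,
    "GBC": 85,
    "HCC": 121,
    "AdvPrC": 533,
    "LocPrC": 1301,
}

STUDY_SEX_FRACTIONS = {
    "BrC": 1.0,
    "CRC": 0.51,
    "EnC": 1.0,
    "KiC": 0.39,
    "GBC": 0.56,
    "HCC": 0.29,
    "AdvPrC": 0.0,
    "LocPrC": 0.0,
}

#: seven studies; colorectal pairs come from two studies, liver-study pairs
#: cover HCC and GBC, and both prostate types come from one prostate study
STUDY_OF_TYPE = {
    "BrC": "breast",
    "CRC": ("crc_1", "crc_2"),
    "EnC": "endometrial",
    "KiC": "kidney",
    "GBC": "liver",
    "HCC": "liver",
    "AdvPrC": "prostate",
    "LocPrC": "prostate",
}


def _default_cluster_spec(rho: float = 0.85) -> list:
    """33 blocks of sizes 2-6 covering 100 of 117 metabolites."""
    sizes = [6] + [5] * 2 + [4] * 5 + [3] * 14 + [2] * 11
    assert sum(sizes) == 100 and len(sizes) == 33
    return [(s, rho) for s in sizes]


def default_config(seed: int = 0, scale: float = 1.0) -> SynthConfig:
    """Study-condition configuration: 8 types, 7 studies, 117 metabolites.

    ``scale`` shrinks the per-type pair counts (never below 40 pairs) for
    desk-scale runs; all other parameters are untouched.
    """
    n_pairs = {t: max(40, int(round(n * scale))) for t, n in STUDY_PAIR_COUNTS.items()}
    p = 117
    mu = np.zeros(p)
    # sparse overall effects: six inverse, three positive (per latent SD)
    for j, v in zip((0, 7, 20, 33, 46, 59), (-0.15, -0.2, -0.25, -0.15, -0.2, -0.25)):
        mu[j] = v
    for j, v in zip((70, 85, 101), (0.15, 0.2, 0.25)):
        mu[j] = v
    delta = {
        "BrC": np.zeros(p),
        "LocPrC": np.zeros(p),
        "HCC": np.zeros(p),
    }
    delta["BrC"][70] = -0.3
    delta["LocPrC"][20] = 0.3
    delta["HCC"][110] = -0.35
    bmi_slope = np.zeros(p)
    bmi_slope[::6] = 0.02  # a fifth of the panel tracks BMI on the log scale
    return SynthConfig(
        n_pairs_per_type=n_pairs,
        n_metabolites=p,
        cluster_spec=_default_cluster_spec(),
        mu_true=mu,
        delta_true=delta,
        bmi_effect_on_metabolite=bmi_slope,
        bmi_log_or={t: 0.03 for t in n_pairs},
        lod_quantile=0.05,
        uloq_quantile=0.995,
        missing_rate=0.01,
        n_batches_per_study=3,
        batch_shift_sd=0.1,
        lod_unknown_rate=0.05,
        study_map=STUDY_OF_TYPE,
        sex_of_type=STUDY_SEX_FRACTIONS,
        hormone_use_rate=0.15,
        seed=seed,
    )


# --------------------------------------------------------------------------
# deterministic fixtures
# --------------------------------------------------------------------------


def _fixture_lod_toy():
    """4 samples x 4 metabolites; one below-LOD cell, one missing cell.

    Batch b1 LOD for ``met_a`` is 0.2, so the censored cell imputes to 0.1;
    the missing ``met_b`` cell imputes to the batch median 2.0 of {1, 2, 4}.
    The missing cell leaves its sample at exactly 25% missingness, so the
    strict sample filter keeps every sample, and the censored cell never
    counts as missing.
    """
    samples = ["s1", "s2", "s3", "s4"]
    names = ["met_a", "met_b", "met_c", "met_d"]
    values = pd.DataFrame(
        {
            "met_a": [0.5, 0.8, np.nan, 0.4],
            "met_b": [1.0, np.nan, 2.0, 4.0],
            "met_c": [0.9, 1.1, 1.0, 1.2],
            "met_d": [3.0, 2.5, 2.8, 3.1],
        },
        index=samples,
    )
    status = pd.DataFrame(
        {
            "met_a": [OBSERVED, OBSERVED, BELOW_LOD, OBSERVED],
            "met_b": [OBSERVED, MISSING, OBSERVED, OBSERVED],
            "met_c": [OBSERVED] * 4,
            "met_d": [OBSERVED] * 4,
        },
        index=samples,
    )
    meta = pd.DataFrame(
        {"quant_class": SEMI_QUANTITATIVE, "chem_class": "PC"},
        index=pd.Index(names, name="metabolite"),
    )
    limits = pd.DataFrame(
        [
            {"batch": "b1", "metabolite": m, "lod": lod, "lloq": np.nan, "uloq": np.nan}
            for m, lod in (("met_a", 0.2), ("met_b", 0.05), ("met_c", 0.05), ("met_d", 0.05))
        ]
    )
    sample_meta = pd.DataFrame(
        {"study": ["s"] * 4, "batch": ["b1"] * 4}, index=pd.Index(samples, name="sample")
    )
    matrix = MetaboliteMatrix(values, status, meta, limits, sample_meta)
    cohort = _toy_cohort([("s1", "s2"), ("s3", "s4")], study="s", batch="b1")
    return matrix, cohort


def _toy_cohort(pairs, study="s", batch="b1", cancer_type="T1"):
    ids = [i for pr in pairs for i in pr]
    pair_df = pd.DataFrame(
        {
            "case_id": [a for a, _ in pairs],
            "control_id": [b for _, b in pairs],
            "study": study,
            "cancer_type": cancer_type,
            "batch": batch,
            "follow_up_years": 5.0,
        },
        index=pd.Index([f"P{i:03d}" for i in range(len(pairs))], name="pair"),
    )
    samples = pd.DataFrame(
        {"bmi": 26.0, "sex": "F", "age": 55.0, "hormone_use": 0},
        index=pd.Index(ids, name="sample"),
    )
    return PairedCohort(pair_df, samples)


def _fixture_two_block():
    """8 variables in two uncorrelated blocks (sizes 4 and 4), 20 pairs.

    Within-block correlation is strong by construction (shared pair-level
    factor plus small noise); across blocks the factors are independent.
    """
    rng = np.random.default_rng(20240803)
    n = 40
    g = rng.standard_normal((n, 2))
    noise = 0.35 * rng.standard_normal((n, 8))
    X = np.empty((n, 8))
    X[:, :4] = g[:, [0]] + noise[:, :4]
    X[:, 4:] = g[:, [1]] + noise[:, 4:]
    names = [f"blkA_{i}" for i in range(4)] + [f"blkB_{i}" for i in range(4)]
    ids = [f"s{i:02d}" for i in range(n)]
    values = pd.DataFrame(np.exp(X), index=ids, columns=names)
    status = pd.DataFrame(OBSERVED, index=ids, columns=names)
    meta = pd.DataFrame(
        {"quant_class": SEMI_QUANTITATIVE, "chem_class": "PC"},
        index=pd.Index(names, name="metabolite"),
    )
    limits = pd.DataFrame(columns=["batch", "metabolite", "lod", "lloq", "uloq"])
    sample_meta = pd.DataFrame(
        {"study": "s", "batch": "b1"}, index=pd.Index(ids, name="sample")
    )
    matrix = MetaboliteMatrix(values, status, meta, limits, sample_meta)
    cohort = _toy_cohort([(ids[2 * i], ids[2 * i + 1]) for i in range(20)])
    return matrix, cohort


def _fixture_single_pair():
    """One matched pair whose log-scale difference vector is (1, -1)."""
    e = float(np.e)
    values = pd.DataFrame(
        {"met_a": [e, 1.0], "met_b": [1.0, e]}, index=["case0", "ctrl0"]
    )
    status = pd.DataFrame(OBSERVED, index=values.index, columns=values.columns)
    meta = pd.DataFrame(
        {"quant_class": SEMI_QUANTITATIVE, "chem_class": "PC"},
        index=pd.Index(["met_a", "met_b"], name="metabolite"),
    )
    limits = pd.DataFrame(columns=["batch", "metabolite", "lod", "lloq", "uloq"])
    sample_meta = pd.DataFrame(
        {"study": "s", "batch": "b1"}, index=pd.Index(values.index, name="sample")
    )
    matrix = MetaboliteMatrix(values, status, meta, limits, sample_meta)
    cohort = _toy_cohort([("case0", "ctrl0")])
    return matrix, cohort


FIXTURES = {
    "lod_toy": _fixture_lod_toy,
    "two_block": _fixture_two_block,
    "single_pair": _fixture_single_pair,
}


def make_fixture(name: str) -> tuple[MetaboliteMatrix, PairedCohort]:
    """Return one of the registered small deterministic test datasets."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return builder()
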