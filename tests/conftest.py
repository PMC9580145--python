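"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pancanmet.containers import (
    OBSERVED,
    SEMI_QUANTITATIVE,
    MetaboliteMatrix,
    PairedCohort,
)
from pancanmet.synth import SynthConfig, generate_cohort


def build_matrix(
    values: pd.DataFrame,
    status: pd.DataFrame | None = None,
    study=None,
    batch=None,
    limits: pd.DataFrame | None = None,
    quant_class: str = SEMI_QUANTITATIVE,
) -> MetaboliteMatrix:
    """Construct a MetaboliteMatrix from a values frame with defaults."""
    if status is None:
        status = pd.DataFrame(OBSERVED, index=values.index, columns=values.columns)
    n = len(values)
    study = ["s1"] * n if study is None else list(study)
    batch = ["b1"] * n if batch is None else list(batch)
    meta = pd.DataFrame(
        {"quant_class": quant_class, "chem_class": "PC"},
        index=pd.Index(values.columns, name="metabolite"),
    )
    if limits is None:
        limits = pd.DataFrame(columns=["batch", "metabolite", "lod", "lloq", "uloq"])
    sample_meta = pd.DataFrame(
        {"study": study, "batch": batch}, index=pd.Index(values.index, name="sample")
    )
    return MetaboliteMatrix(values, status, meta, limits, sample_meta)


def build_cohort(pairs, cancer_type="T1", study="s1", batch="b1",
                 follow_up=5.0, bmi=None, extra=None) -> PairedCohort:
    """Matched cohort from [(case_id, control_id), ...] tuples."""
    pairs = list(pairs)
    if np.isscalar(cancer_type):
        cancer_type = [cancer_type] * len(pairs)
    if np.isscalar(follow_up):
        follow_up = [follow_up] * len(pairs)
    pair_df = pd.DataFrame(
        {
            "case_id": [a for a, _ in pairs],
            "control_id": [b for _, b in pairs],
            "study": study,
            "cancer_type": cancer_type,
            "batch": batch,
            "follow_up_years": follow_up,
        },
        index=pd.Index([f"P{i:04d}" for i in range(len(pairs))], name="pair"),
    )
    ids = [s for pr in pairs for s in pr]
    samples = pd.DataFrame(
        {"bmi": 26.0 if bmi is None else bmi, "sex": "F", "age": 55.0, "hormone_use": 0},
        index=pd.Index(ids, name="sample"),
    )
    if extra:
        for k, v in extra.items():
            samples[k] = v
    return PairedCohort(pair_df, samples)


def simulate_pairs(
    rng: np.random.Generator,
    n_pairs: int,
    beta: np.ndarray,
    types=None,
    bmi_sd: float = 0.0,
    bmi_log_or: float = 0.0,
):
    """Minimal matched-pair simulator used by calibration/power checks.

    Feature values are standard normal per sample; within each pair the
    case is the member with probability sigma(eta_1 - eta_2).  Returns
    (features DataFrame indexed by sample, PairedCohort).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = len(beta)
    X = rng.standard_normal((n_pairs, 2, p))
    bmi = 26.0 + bmi_sd * rng.standard_normal((n_pairs, 2))
    eta = X @ beta + bmi_log_or * (bmi - 26.0)
    case_first = rng.random(n_pairs) < 1.0 / (1.0 + np.exp(-(eta[:, 0] - eta[:, 1])))
    ids = np.array([f"s{i:05d}" for i in range(2 * n_pairs)]).reshape(n_pairs, 2)
    case = np.where(case_first, ids[:, 0], ids[:, 1])
    ctrl = np.where(case_first, ids[:, 1], ids[:, 0])
    feats = pd.DataFrame(
        X.reshape(2 * n_pairs, p),
        index=ids.reshape(-1),
        columns=[f"f{j}" for j in range(p)],
    )
    cohort = build_cohort(
        list(zip(case, ctrl)),
        cancer_type=(list(types) if types is not None else "T1"),
        bmi=bmi.reshape(-1),
    )
    return feats, cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small multi-type synthetic cohort with effects, shared per session."""
    p = 12
    mu = np.zeros(p)
    mu[0], mu[5] = 0.4, -0.4
    config = SynthConfig(
        n_pairs_per_type={"T1": 150, "T2": 150},
        n_metabolites=p,
        cluster_spec=[(3, 0.8)],
        mu_true=mu,
        bmi_log_or={"T1": 0.03, "T2": 0.03},
        seed=42,
    )
    matrix, cohort, truth = generate_cohort(config)
    return matrix, cohort, truth
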