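"""In-memory containers for targeted-metabolomics matched case-control data.

Two objects travel through the whole pipeline:

``MetaboliteMatrix``
    A samples x metabolites concentration table with a parallel per-cell
    status table (observed / censored / missing), per-metabolite assay
    metadata (semi- vs fully-quantitative, chemical class) and a per
    (batch, metabolite) table of quantification limits (LOD for
    semi-quantitative assays, LLOQ/ULOQ for fully quantitative ones).

``PairedCohort``
    The matched 1:1 case-control design: one row per pair carrying study,
    cancer type, batch and follow-up time, plus a per-sample covariate
    table (BMI, sex, hormone use, lifestyle covariates).

Both round-trip through plain delimited text (TSV) with a JSON sidecar for
the limits table, which is the on-disk interchange format of the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

# Per-cell status codes
OBSERVED = "observed"
BELOW_LOD = "below_lod"
BELOW_LLOQ = "below_lloq"
ABOVE_ULOQ = "above_uloq"
MISSING = "missing"

STATUS_CODES = (OBSERVED, BELOW_LOD, BELOW_LLOQ, ABOVE_ULOQ, MISSING)
CENSORED = (BELOW_LOD, BELOW_LLOQ, ABOVE_ULOQ)

SEMI_QUANTITATIVE = "semi_quantitative"
FULLY_QUANTITATIVE = "fully_quantitative"


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites concentrations with censoring/missingness status.

    Parameters
    ----------
    values : DataFrame (samples x metabolites)
        Concentrations. Cells whose status is not ``observed`` hold NaN until
        an imputation step fills them.
    status : DataFrame (samples x metabolites)
        One of the five status codes per cell.
    metabolite_meta : DataFrame indexed by metabolite
        Columns ``quant_class`` (semi_quantitative / fully_quantitative) and
        ``chem_class`` (free-text chemical class label).
    limits : DataFrame
        One row per (batch, metabolite) with columns ``batch``,
        ``metabolite``, ``lod``, ``lloq``, ``uloq`` (NaN where not
        applicable or unknown).
    sample_meta : DataFrame indexed by sample
        Columns ``study`` and ``batch``.
    """

    values: pd.DataFrame
    status: pd.DataFrame
    metabolite_meta: pd.DataFrame
    limits: pd.DataFrame
    sample_meta: pd.DataFrame
    #: True once a log transform has been applied (values may then be <= 0)
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.status.index) or not self.values.columns.equals(
            self.status.columns
        ):
            raise ValueError("values and status must share index and columns")
        missing_meta = set(self.values.columns) - set(self.metabolite_meta.index)
        if missing_meta:
            raise ValueError(f"metabolite_meta missing entries for {sorted(missing_meta)[:5]}")
        missing_samples = set(self.values.index) - set(self.sample_meta.index)
        if missing_samples:
            raise ValueError(f"sample_meta missing entries for {sorted(missing_samples)[:5]}")
        bad = self.values.values[(self.status.values == OBSERVED)]
        if bad.size and not np.all(np.isfinite(bad)):
            raise ValueError("observed cells must hold finite values")
        if not self.log_scale and bad.size and not np.all(bad > 0):
            raise ValueError("observed cells must hold finite positive concentrations")

    # ------------------------------------------------------------------ views
    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.values.copy(),
            self.status.copy(),
            self.metabolite_meta.copy(),
            self.limits.copy(),
            self.sample_meta.copy(),
            log_scale=self.log_scale,
        )

    def subset(self, samples=None, metabolites=None) -> "MetaboliteMatrix":
        """Restrict to the given samples and/or metabolites (order preserved)."""
        samples = self.samples if samples is None else pd.Index(samples)
        metabolites = self.metabolites if metabolites is None else pd.Index(metabolites)
        limits = self.limits[self.limits["metabolite"].isin(metabolites)].reset_index(drop=True)
        return MetaboliteMatrix(
            self.values.loc[samples, metabolites].copy(),
            self.status.loc[samples, metabolites].copy(),
            self.metabolite_meta.loc[metabolites].copy(),
            limits,
            self.sample_meta.loc[samples].copy(),
            log_scale=self.log_scale,
        )

    def limit_lookup(self, kind: str) -> pd.Series:
        """Return a Series of limit values indexed by (batch, metabolite)."""
        sub = self.limits.dropna(subset=[kind])
        return sub.set_index(["batch", "metabolite"])[kind]

    # ------------------------------------------------------------------- I/O
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(path / "values.tsv", sep="\t")
        self.status.to_csv(path / "status.tsv", sep="\t")
        self.metabolite_meta.to_csv(path / "metabolite_meta.tsv", sep="\t")
        self.sample_meta.to_csv(path / "sample_meta.tsv", sep="\t")
        records = self.limits.to_dict(orient="records")
        clean = [
            {k: (None if (isinstance(v, float) and np.isnan(v)) else v) for k, v in r.items()}
            for r in records
        ]
        (path / "limits.json").write_text(json.dumps(clean, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "MetaboliteMatrix":
        path = Path(path)
        values = pd.read_csv(path / "values.tsv", sep="\t", index_col=0)
        status = pd.read_csv(path / "status.tsv", sep="\t", index_col=0)
        meta = pd.read_csv(path / "metabolite_meta.tsv", sep="\t", index_col=0)
        sample_meta = pd.read_csv(path / "sample_meta.tsv", sep="\t", index_col=0)
        limits = pd.DataFrame(json.loads((path / "limits.json").read_text()))
        for col in ("lod", "lloq", "uloq"):
            if col not in limits.columns:
                limits[col] = np.nan
        return cls(values, status, meta, limits, sample_meta)


@dataclass
class PairedCohort:
    """Matched 1:1 case-control pairs with per-sample covariates.

    ``pairs`` is indexed by pair id with columns ``case_id``, ``control_id``,
    ``study``, ``cancer_type``, ``batch``, ``follow_up_years``.  ``samples``
    is indexed by sample id and carries at least ``bmi``; typical extra
    columns are ``sex``, ``age``, ``hormone_use`` and lifestyle covariates
    used by the sensitivity analyses.
    """

    pairs: pd.DataFrame
    samples: pd.DataFrame

    REQUIRED_PAIR_COLS = ("case_id", "control_id", "study", "cancer_type", "batch")

    def __post_init__(self) -> None:
        for col in self.REQUIRED_PAIR_COLS:
            if col not in self.pairs.columns:
                raise ValueError(f"pairs table missing required column {col!r}")
        ids = pd.concat([self.pairs["case_id"], self.pairs["control_id"]])
        if ids.duplicated().any():
            raise ValueError("each sample may appear in exactly one pair")
        unknown = set(ids) - set(self.samples.index)
        if unknown:
            raise ValueError(f"samples table missing entries for {sorted(unknown)[:5]}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def types(self) -> list:
        """Cancer types in first-appearance order."""
        return list(pd.unique(self.pairs["cancer_type"]))

    @property
    def case_ids(self) -> pd.Index:
        return pd.Index(self.pairs["case_id"])

    @property
    def control_ids(self) -> pd.Index:
        return pd.Index(self.pairs["control_id"])

    @property
    def sample_ids(self) -> pd.Index:
        return self.case_ids.append(self.control_ids)

    def pairs_per_type(self) -> pd.Series:
        return self.pairs["cancer_type"].value_counts()

    def subset(self, pair_ids) -> "PairedCohort":
        pairs = self.pairs.loc[pair_ids].copy()
        keep = pd.Index(pairs["case_id"]).append(pd.Index(pairs["control_id"]))
        return PairedCohort(pairs, self.samples.loc[keep].copy())

    def copy(self) -> "PairedCohort":
        return PairedCohort(self.pairs.copy(), self.samples.copy())

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(path / "pairs.tsv", sep="\t")
        self.samples.to_csv(path / "samples.tsv", sep="\t")

    @classmethod
    def from_dir(cls, path: str | Path) -> "PairedCohort":
        path = Path(path)
        pairs = pd.read_csv(path / "pairs.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col=0)
        return cls(pairs, samples)
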