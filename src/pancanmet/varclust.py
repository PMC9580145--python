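"""Hierarchical clustering of variables with first-PC representatives.

Variables (metabolites, on the log scale) are grouped agglomeratively.  The
homogeneity of a cluster is the leading eigenvalue ``lambda_1`` of its
correlation matrix, equivalently ``max_y sum_j corr^2(x_j, y)`` over
synthetic scores ``y``; the share of cluster variance explained by its
first-principal-component representative is ``lambda_1 / p``.  Each merge
joins the pair of clusters losing the least total homogeneity, and the
retained partition is the one with the fewest clusters in which every
representative explains at least 80% (configurable) of its cluster's
variance.

The correlation substrate is computed on control samples only (cases are
scored afterwards with control-derived standardisation), which avoids
conditioning the correlation structure on case status.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def cluster_homogeneity(X: np.ndarray) -> tuple[float, np.ndarray]:
    """Explained-variance share and loadings of a variable block.

    Parameters
    ----------
    X : array (rows x variables)
        Variables standardized over the supplied rows.

    Returns
    -------
    explained_share : float
        ``lambda_1 / p`` with ``lambda_1`` the leading eigenvalue of the
        block's correlation matrix.
    loadings : array
        Unit-norm leading eigenvector, oriented so its mean is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if p == 0:
        raise ValueError("empty variable block")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance variable in block")
    if p == 1:
        return 1.0, np.array([1.0])
    R = np.corrcoef(X, rowvar=False)
    lam, vec = _leading_eig(R)
    return lam / p, vec


def _leading_eig(R: np.ndarray) -> tuple[float, np.ndarray]:
    w, V = np.linalg.eigh(R)
    vec = V[:, -1]
    s = vec.mean()
    if s < 0 or (s == 0 and vec[0] < 0):
        vec = -vec
    return float(w[-1]), vec


@dataclass
class MergeTree:
    """Agglomeration sequence over variables.

    ``merges`` holds, per step, the two merged clusters (sorted label
    tuples), the resulting cluster, the homogeneity loss of the merge and
    the total homogeneity after it.  ``corr`` is the variable correlation
    matrix the tree was grown on.
    """

    labels: list
    corr: pd.DataFrame
    merges: list = field(default_factory=list)

    def partition_at(self, n_clusters: int) -> list[tuple]:
        """Cluster composition after unwinding merges down to ``n_clusters``."""
        p = len(self.labels)
        if not (1 <= n_clusters <= p):
            raise ValueError(f"n_clusters must be in [1, {p}]")
        clusters = [(l,) for l in self.labels]
        for step in self.merges[: p - n_clusters]:
            clusters = [c for c in clusters if c != step["left"] and c != step["right"]]
            clusters.append(step["merged"])
        return sorted(clusters)


def build_merge_tree(X: pd.DataFrame) -> MergeTree:
    """Grow the full agglomeration tree on (controls-only) data.

    At each step the pair of clusters whose merge minimises the loss of
    total homogeneity (sum of leading eigenvalues) is joined.  Ties are
    broken lexicographically by the merged cluster's smallest member
    labels, so the tree is deterministic across platforms.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables to build a merge tree")
    labels = list(X.columns)
    sd = X.values.std(axis=0)
    if np.any(sd == 0):
        bad = [l for l, s in zip(labels, sd) if s == 0]
        raise ValueError(f"zero-variance variable(s): {bad[:5]}")
    R = pd.DataFrame(np.corrcoef(X.values, rowvar=False), index=labels, columns=labels)
    tree = MergeTree(labels=labels, corr=R)

    clusters: list[tuple] = [(l,) for l in labels]
    homog = {c: 1.0 for c in clusters}
    Rv = R.values
    pos = {l: i for i, l in enumerate(labels)}

    def lam1(members: tuple) -> float:
        if len(members) == 1:
            return 1.0
        idx = [pos[l] for l in members]
        sub = Rv[np.ix_(idx, idx)]
        if len(idx) == 2:
            return 1.0 + abs(sub[0, 1])
        return float(np.linalg.eigvalsh(sub)[-1])

    # cached merge losses; only pairs touching the newest cluster change
    pair_h: dict = {}
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i], clusters[j]
            pair_h[(a, b)] = lam1(tuple(sorted(a + b)))

    total = float(len(labels))
    while len(clusters) > 1:
        best = None  # (loss, merged_labels, left, right, h_merged)
        for (a, b), h in pair_h.items():
            loss = homog[a] + homog[b] - h
            merged = tuple(sorted(a + b))
            if (
                best is None
                or loss < best[0] - 1e-12
                or (abs(loss - best[0]) <= 1e-12 and merged < best[1])
            ):
                best = (loss, merged, a, b, h)
        loss, merged, left, right, h = best
        total -= loss
        tree.merges.append(
            {
                "left": left,
                "right": right,
                "merged": merged,
                "loss": float(loss),
                "homogeneity_after": float(total),
            }
        )
        clusters = [c for c in clusters if c not in (left, right)]
        pair_h = {
            pair: h_
            for pair, h_ in pair_h.items()
            if left not in pair and right not in pair
        }
        for c in clusters:
            pair_h[(c, merged)] = lam1(tuple(sorted(c + merged)))
        clusters.append(merged)
        homog[merged] = h
    return tree


@dataclass
class ClusterModel:
    """A selected variable partition with PC-representative scoring rules.

    ``assignment`` maps each metabolite to a feature name (``xxx_clus`` for
    clusters of two or more, where ``xxx`` is the lexicographically first
    member; the metabolite's own name when isolated).  ``loadings`` holds,
    per feature, the unit-norm weights over member variables; scoring
    standardizes members with the control-derived ``means``/``sds`` and
    applies the loadings.
    """

    assignment: dict
    loadings: dict  # feature -> {metabolite: weight}
    explained_share: dict  # feature -> float
    means: pd.Series
    sds: pd.Series
    merge_tree: MergeTree | None = None

    @property
    def features(self) -> list:
        return sorted(self.loadings)

    @property
    def clusters(self) -> dict:
        """feature -> tuple of member metabolites."""
        out: dict = {}
        for metab, feat in self.assignment.items():
            out.setdefault(feat, []).append(metab)
        return {f: tuple(sorted(ms)) for f, ms in out.items()}

    def n_clusters(self) -> int:
        return sum(1 for ms in self.clusters.values() if len(ms) > 1)

    def n_isolated(self) -> int:
        return sum(1 for ms in self.clusters.values() if len(ms) == 1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignment": self.assignment,
            "loadings": self.loadings,
            "explained_share": self.explained_share,
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            assignment=payload["assignment"],
            loadings=payload["loadings"],
            explained_share=payload["explained_share"],
            means=pd.Series(payload["means"]),
            sds=pd.Series(payload["sds"]),
        )


def _feature_name(members: tuple) -> str:
    return members[0] if len(members) == 1 else f"{min(members)}_clus"


def select_partition(
    tree: MergeTree,
    X: pd.DataFrame,
    min_explained: float = 0.80,
) -> ClusterModel:
    """Smallest-cluster-count tree cut whose every representative explains
    at least ``min_explained`` of its cluster's variance.

    Scanning starts from the single-cluster partition and unwinds merges;
    the all-singletons partition always satisfies the rule, so the scan
    terminates.  ``X`` must be the same (controls-only) rows the tree was
    grown on; its means/SDs become the scoring standardisation.
    """
    p = len(tree.labels)
    pos = {l: i for i, l in enumerate(tree.labels)}
    Rv = tree.corr.values
    chosen = None
    for k in range(1, p + 1):
        part = tree.partition_at(k)
        ok = True
        for members in part:
            if len(members) > 1:
                idx = [pos[l] for l in members]
                lam = float(np.linalg.eigvalsh(Rv[np.ix_(idx, idx)])[-1])
                if lam / len(members) < min_explained - 1e-12:
                    ok = False
                    break
        if ok:
            chosen = part
            break
    assignment: dict = {}
    loadings: dict = {}
    shares: dict = {}
    for members in chosen:
        name = _feature_name(members)
        if len(members) == 1:
            lam_share, vec = 1.0, np.array([1.0])
        else:
            idx = [pos[l] for l in members]
            lam, vec = _leading_eig(Rv[np.ix_(idx, idx)])
            lam_share = lam / len(members)
        for metab, w in zip(members, vec):
            assignment[metab] = name
        loadings[name] = {metab: float(w) for metab, w in zip(members, vec)}
        shares[name] = float(lam_share)
    return ClusterModel(
        assignment=assignment,
        loadings=loadings,
        explained_share=shares,
        means=X.mean(),
        sds=X.std(ddof=1),
        merge_tree=tree,
    )


def fit_varclust(
    features: pd.DataFrame,
    control_ids=None,
    min_explained: float = 0.80,
) -> ClusterModel:
    """Cluster variables on control rows and select the retained partition."""
    rows = features if control_ids is None else features.loc[control_ids]
    tree = build_merge_tree(rows)
    return select_partition(tree, rows, min_explained=min_explained)


def score_representatives(features: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    """Samples x features matrix of cluster scores and isolated metabolites.

    Member variables are standardized with the control-derived means/SDs
    stored in the model, then combined with the unit-norm loadings; an
    isolated metabolite's feature is simply its standardized value.
    """
    needed = set(model.assignment)
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"features missing clustered metabolites: {sorted(missing)[:5]}")
    std = (features[list(model.means.index)] - model.means) / model.sds
    out = {}
    for feat, wmap in model.loadings.items():
        members = list(wmap)
        w = np.array([wmap[m] for m in members])
        out[feat] = std[members].values @ w
    return pd.DataFrame(out, index=features.index)[model.features]


def cluster_heatmap_table(model: ClusterModel, X_controls: pd.DataFrame) -> pd.DataFrame:
    """Member-vs-representative correlation table (cluster composition export)."""
    scores = score_representatives(X_controls, model)
    rows = []
    for feat, members in sorted(model.clusters.items()):
        for m in members:
            r = float(np.corrcoef(X_controls[m], scores[feat])[0, 1])
            rows.append({"feature": feat, "metabolite": m, "correlation": r})
    return pd.DataFrame(rows)
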