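"""Within-instrument item structure: correlation, regrouping, QoL clustering.

The first stage of the portrait construction asks, per instrument, which
individual test scores move together.  Correlation is rank-based
(Spearman), appropriate for ordinal item scores, and is pooled over all
patient-visits — each visit is treated as an observation because the goal
is cross-sectional association between items, not longitudinal inference.
Items whose correlation exceeds a threshold (0.5 by default, with 0.35 the
conventional alternative for the weaker within-muscle-group regime) are
regrouped into blocks by connected components.

The 15 quality-of-life items are so strongly inter-correlated that
pairwise regrouping would collapse them into one uninformative block;
instead their per-visit profiles are clustered (k-means) into a small
number of fatigue patterns, ordered from least to most severe, with the
silhouette and the monotone progression of centroids used to judge the
cluster count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .schema import ScoreTable, SchemaError, get_instrument

__all__ = [
    "CorrelationResult",
    "ItemGrouping",
    "QoLClusterModel",
    "correlation_matrix",
    "regroup_strong_pairs",
    "cluster_qol",
    "centroid_monotonicity",
    "select_qol_k",
]


@dataclass
class CorrelationResult:
    """Pairwise Spearman correlation between items of one instrument."""

    instrument: str
    rho: pd.DataFrame
    pval: pd.DataFrame
    n_pairs: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "items": list(self.rho.index),
            "rho": self.rho.to_numpy().tolist(),
            "pval": self.pval.to_numpy().tolist(),
            "n_pairs": self.n_pairs.to_numpy().tolist(),
        }


def correlation_matrix(
    table: ScoreTable, instrument: str, min_pairs: int = 3
) -> CorrelationResult:
    """Spearman correlation between items, pooled over patient-visit(-rater) records.

    Cells with fewer than ``min_pairs`` complete pairs are left missing.
    """
    wide = table.wide(instrument)
    items = list(wide.columns)
    m = len(items)
    rho = np.full((m, m), np.nan)
    pval = np.full((m, m), np.nan)
    npairs = np.zeros((m, m), dtype=int)
    X = wide.to_numpy(dtype=float)
    for i in range(m):
        rho[i, i] = 1.0
        pval[i, i] = 0.0
        npairs[i, i] = int(np.isfinite(X[:, i]).sum())
        for j in range(i + 1, m):
            mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            npairs[i, j] = npairs[j, i] = int(mask.sum())
            if mask.sum() < min_pairs:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant input -> nan, kept as missing
                r, p = stats.spearmanr(X[mask, i], X[mask, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(items, name="item_id")
    return CorrelationResult(
        instrument=instrument,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        pval=pd.DataFrame(pval, index=idx, columns=idx),
        n_pairs=pd.DataFrame(npairs, index=idx, columns=idx),
    )


@dataclass
class ItemGrouping:
    """Partition of an instrument's items into correlated blocks."""

    instrument: str
    groups: list[list[str]]
    threshold_used: float
    alpha_used: float

    @property
    def blocks(self) -> list[frozenset]:
        return [frozenset(g) for g in self.groups]

    def to_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "groups": [list(g) for g in self.groups],
            "threshold_used": self.threshold_used,
            "alpha_used": self.alpha_used,
        }


def regroup_strong_pairs(
    corr: CorrelationResult, rho_threshold: float = 0.5, alpha: float = 0.01
) -> ItemGrouping:
    """Regroup items connected by strong, significant correlations.

    Blocks are the connected components of the graph with an edge wherever
    ``rho >= rho_threshold`` and ``pval <= alpha``; items without any
    qualifying edge stay singletons.
    """
    if not 0.0 < rho_threshold <= 1.0:
        raise ValueError(f"rho_threshold must be in (0, 1], got {rho_threshold}")
    items = list(corr.rho.index)
    R = corr.rho.to_numpy()
    P = corr.pval.to_numpy()
    adj = np.zeros_like(R, dtype=bool)
    with np.errstate(invalid="ignore"):
        adj = (R >= rho_threshold) & (P <= alpha)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: list[list[str]] = []
    for c in range(n_comp):
        members = [items[i] for i in np.flatnonzero(labels == c)]
        groups.append(members)
    # deterministic order: by first member's position in the instrument
    groups.sort(key=lambda g: items.index(g[0]))
    return ItemGrouping(
        instrument=corr.instrument,
        groups=groups,
        threshold_used=rho_threshold,
        alpha_used=alpha,
    )


@dataclass
class QoLClusterModel:
    """Fatigue patterns: k-means clusters of per-visit QoL item profiles.

    Cluster labels are 1..k ordered by ascending centroid mean, so cluster 1
    is the least severe pattern.
    """

    k: int
    assignments: pd.Series  # (patient_id, visit_month[, rater]) -> 1..k
    centroids: pd.DataFrame  # index 1..k, columns item ids
    silhouette: np.ndarray
    cluster_order: list[int]  # severity rank -> original k-means label
    mean_silhouette: float
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "assignments": {
                "|".join(str(p) for p in key): int(v)
                for key, v in self.assignments.items()
            },
            "centroids": {str(i): row.tolist() for i, row in self.centroids.iterrows()},
            "items": list(self.centroids.columns),
            "cluster_order": list(self.cluster_order),
            "mean_silhouette": self.mean_silhouette,
            "degenerate": self.degenerate,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QoLClusterModel":
        keys = []
        vals = []
        for key, v in d["assignments"].items():
            pid, month, rater = key.split("|")
            keys.append((pid, float(month), rater))
            vals.append(int(v))
        idx = pd.MultiIndex.from_tuples(
            keys, names=["patient_id", "visit_month", "rater_id"]
        )
        centroids = pd.DataFrame.from_dict(d["centroids"], orient="index")
        centroids.index = centroids.index.astype(int)
        centroids = centroids.sort_index()
        centroids.columns = d["items"]
        centroids.index.name = "cluster"
        return cls(
            k=int(d["k"]),
            assignments=pd.Series(vals, index=idx, name="cluster"),
            centroids=centroids,
            silhouette=np.array([]),  # per-sample silhouettes are not serialized
            cluster_order=[int(o) for o in d.get("cluster_order", range(d["k"]))],
            mean_silhouette=float(d["mean_silhouette"]),
            degenerate=bool(d.get("degenerate", False)),
            warnings=list(d.get("warnings", [])),
        )


def _qol_wide(table: ScoreTable) -> pd.DataFrame:
    wide = table.wide("MG-QOL15")
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            f"incomplete MG-QOL15 vectors at {len(incomplete)} patient-visits, "
            f"e.g. {list(incomplete[:5])}; clustering needs complete item profiles"
        )
    return wide


def cluster_qol(
    table: ScoreTable, k: int, seed: int = 0, n_init: int = 20
) -> QoLClusterModel:
    """Cluster complete per-visit QoL item profiles into ``k`` fatigue patterns.

    Plain k-means on raw item scores (Euclidean metric) with multiple
    restarts; silhouettes computed on the same metric.  Clusters are
    relabeled 1..k by ascending centroid mean.
    """
    wide = _qol_wide(table)
    n = len(wide)
    if k < 2 or k >= n:
        raise ValueError(f"need 2 <= k < n_samples ({n}), got k={k}")
    X = wide.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(X)
    if len(np.unique(raw_labels)) > 1:
        sil = silhouette_samples(X, raw_labels)
    else:  # degenerate: every sample in one effective cluster
        sil = np.zeros(n)
    centroid_means = km.cluster_centers_.mean(axis=1)
    order = list(np.argsort(centroid_means, kind="stable"))
    relabel = {orig: rank + 1 for rank, orig in enumerate(order)}
    labels = np.array([relabel[l] for l in raw_labels])
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=wide.columns,
    )
    warn: list[str] = []
    dists = np.linalg.norm(
        centroids.to_numpy()[:, None, :] - centroids.to_numpy()[None, :, :], axis=-1
    )
    np.fill_diagonal(dists, np.inf)
    degenerate = bool((dists < 1e-8).any())
    if degenerate:
        warn.append("duplicate centroids: clustering is degenerate for this k")
    return QoLClusterModel(
        k=k,
        assignments=pd.Series(labels, index=wide.index, name="cluster"),
        centroids=centroids,
        silhouette=sil,
        cluster_order=[int(o) for o in order],
        mean_silhouette=float(sil.mean()),
        degenerate=degenerate,
        warnings=warn,
    )


def centroid_monotonicity(model: QoLClusterModel, tol: float = 1e-9) -> tuple[bool, list[str]]:
    """True iff every item's centroid value is non-decreasing along the
    severity-ordered clusters; otherwise lists the violating items."""
    C = model.centroids.to_numpy()
    diffs = np.diff(C, axis=0)
    bad = np.flatnonzero((diffs < -tol).any(axis=0))
    violating = [model.centroids.columns[j] for j in bad]
    return len(violating) == 0, violating


def select_qol_k(
    table: ScoreTable,
    k_range: Iterable[int],
    seed: int = 0,
    target_instrument: str = "MG-ADL",
) -> int:
    """Largest cluster count that keeps the QoL patterns orderable.

    A candidate ``k`` qualifies when the centroid progression is monotone
    and — when the table also carries the target instrument — the fitted
    cluster-to-total map has non-decreasing cluster means.  Returns the
    largest qualifying ``k``; if none qualifies, returns ``min(k_range)``
    with a warning.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > 8:
        raise ValueError(f"k_range must lie within 2..8, got {ks}")
    from .maps import EstimationError, fit_cluster_score_map

    has_target = (table.df["instrument"] == target_instrument).any()
    for k in reversed(ks):
        model = cluster_qol(table, k, seed=seed)
        mono, _ = centroid_monotonicity(model)
        if not mono or model.degenerate:
            continue
        if has_target:
            try:
                cs = fit_cluster_score_map(model, table, target_instrument)
            except EstimationError:
                cs = None
            if cs is not None and not cs.monotone:
                continue
        return k
    warnings.warn(
        f"no k in {ks} gives monotone QoL patterns; falling back to k={ks[0]}",
        stacklevel=2,
    )
    return ks[0]
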