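"""Stochastic maps between ordinal score items.

A *stochastic map* is a row-stochastic matrix ``P[x, y] = Pr(target = y |
source = x)`` estimated by enumeration counts over all (patient, visit,
rater) pairings in which both items were observed.  Maps are always
estimated per direction from the same pairings, never by matrix inversion,
so the direct- and inverse-map count matrices are exact transposes of each
other.

Rows of the source domain that were never observed carry no information;
they fall back to the target's empirical marginal distribution and are
flagged, so downstream consumers can distinguish data-driven rows from
prior-filled ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .schema import Instrument, Item, ScoreTable, get_instrument

if TYPE_CHECKING:  # pragma: no cover
    from .structure import QoLClusterModel

__all__ = [
    "ItemRef",
    "StochasticMap",
    "JointScoreDistribution",
    "ClusterScoreMap",
    "MapDiagnostics",
    "EstimationError",
    "estimate_map",
    "impute_item",
    "estimate_joint",
    "map_diagnostics",
    "fit_cluster_score_map",
    "sample_qol_from_level",
    "DEFAULT_CORRESPONDENCE",
]


class EstimationError(ValueError):
    """No usable pairings between the two items."""


class ItemRef(NamedTuple):
    """An (instrument, item) reference."""

    instrument: str
    item_id: str


#: Cross-instrument item correspondences with a meaningful clinical match:
#: the ocular items scored by both MG-ADL and QMG, and sustained speech.
#: The MG-CE cheek-puff test is deliberately not mapped anywhere because of
#: its poor reliability.
DEFAULT_CORRESPONDENCE: tuple[tuple[ItemRef, ItemRef], ...] = (
    (ItemRef("QMG", "ptosis"), ItemRef("MG-ADL", "eyelid_drop")),
    (ItemRef("QMG", "vision"), ItemRef("MG-ADL", "double_vision")),
    (ItemRef("QMG", "speech"), ItemRef("MG-ADL", "talking")),
)


def _item(ref: ItemRef, instruments: Sequence[Instrument] | None = None) -> Item:
    return get_instrument(ref.instrument, instruments).item(ref.item_id)


def _pairings(table: ScoreTable, source: ItemRef, target: ItemRef) -> pd.DataFrame:
    """Observed (source value, target value) pairs joined on (patient, visit, rater)."""
    df = table.observed()
    key = ["patient_id", "visit_month", "rater_id"]

    def side(ref: ItemRef, name: str) -> pd.DataFrame:
        sub = df[(df["instrument"] == ref.instrument) & (df["item_id"] == ref.item_id)]
        sub = sub[key + ["value"]].copy()
        sub["rater_id"] = sub["rater_id"].fillna("")
        return sub.rename(columns={"value": name})

    a = side(source, "x")
    b = side(target, "y")
    merged = a.merge(b, on=key, how="inner")
    return merged


@dataclass
class StochasticMap:
    """Row-stochastic conditional map ``P[x, y] = Pr(y | x)``."""

    source: ItemRef
    target: ItemRef
    source_domain: tuple[int, ...]
    target_domain: tuple[int, ...]
    counts: np.ndarray  # (|X|, |Y|) integer pairing counts
    P: np.ndarray  # (|X|, |Y|) row-stochastic
    row_support: np.ndarray  # (|X|,) pairings per source value
    marginal_filled: np.ndarray  # (|X|,) bool, True where row fell back to the marginal
    smoothing: str = "none"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.source_domain), len(self.target_domain)):
            raise ValueError("P shape inconsistent with domains")
        if (self.P < 0).any():
            raise ValueError("negative probabilities in P")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of P must sum to 1")

    def row(self, x: int) -> np.ndarray:
        if x not in self.source_domain:
            raise ValueError(f"{x} outside source domain {self.source_domain}")
        return self.P[self.source_domain.index(x)]

    def to_dict(self) -> dict:
        return {
            "source": list(self.source),
            "target": list(self.target),
            "source_domain": list(self.source_domain),
            "target_domain": list(self.target_domain),
            "counts": self.counts.tolist(),
            "P": self.P.tolist(),
            "row_support": self.row_support.tolist(),
            "marginal_filled": [bool(b) for b in self.marginal_filled],
            "smoothing": self.smoothing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StochasticMap":
        return cls(
            source=ItemRef(*d["source"]),
            target=ItemRef(*d["target"]),
            source_domain=tuple(d["source_domain"]),
            target_domain=tuple(d["target_domain"]),
            counts=np.asarray(d["counts"]),
            P=np.asarray(d["P"], dtype=float),
            row_support=np.asarray(d["row_support"]),
            marginal_filled=np.asarray(d["marginal_filled"], dtype=bool),
            smoothing=d.get("smoothing", "none"),
        )


def map_from_counts(
    counts: np.ndarray,
    source: ItemRef,
    target: ItemRef,
    source_domain: Sequence[int],
    target_domain: Sequence[int],
    pseudo_count: float = 0.0,
) -> StochasticMap:
    """Row-normalize a count matrix into a :class:`StochasticMap`.

    Zero-support rows fall back to the target's empirical marginal (from the
    grand count totals) and are flagged.  ``pseudo_count`` adds optional
    additive smoothing; the default is raw enumeration.
    """
    counts = np.asarray(counts, dtype=float)
    row_support = counts.sum(axis=1)
    total = counts.sum()
    if total <= 0:
        raise EstimationError(f"no pairings between {source} and {target}")
    marginal = counts.sum(axis=0) / total
    smoothed = counts + pseudo_count
    with np.errstate(invalid="ignore", divide="ignore"):
        P = smoothed / smoothed.sum(axis=1, keepdims=True)
    filled = row_support + pseudo_count * counts.shape[1] <= 0
    P[filled] = marginal
    return StochasticMap(
        source=source,
        target=target,
        source_domain=tuple(int(v) for v in source_domain),
        target_domain=tuple(int(v) for v in target_domain),
        counts=counts.astype(int),
        P=P,
        row_support=row_support.astype(int),
        marginal_filled=filled,
        smoothing="none" if pseudo_count == 0 else f"pseudo_count={pseudo_count:g}",
    )


def estimate_map(
    table: ScoreTable,
    source: ItemRef,
    target: ItemRef,
    pseudo_count: float = 0.0,
) -> StochasticMap:
    """Estimate ``Pr(target | source)`` by enumeration counts.

    Every (patient, visit, rater) pairing with both items observed counts
    once; replicate rater scores therefore contribute one pairing each.
    """
    src_item = _item(source, table.instruments)
    tgt_item = _item(target, table.instruments)
    pairs = _pairings(table, source, target)
    if pairs.empty:
        raise EstimationError(f"no pairings between {source} and {target}")
    counts = np.zeros((src_item.n_levels, tgt_item.n_levels))
    np.add.at(
        counts,
        (
            pairs["x"].to_numpy(int) - src_item.lo,
            pairs["y"].to_numpy(int) - tgt_item.lo,
        ),
        1,
    )
    return map_from_counts(
        counts, source, target, src_item.domain, tgt_item.domain, pseudo_count
    )


def impute_item(smap: StochasticMap, x: int) -> tuple[np.ndarray, bool]:
    """Distribution over the target domain given source value ``x``.

    Returns ``(probs, marginal_filled)``; the flag is True when the row had
    zero support and carries only the target marginal.
    """
    probs = smap.row(int(x)).copy()
    flagged = bool(smap.marginal_filled[smap.source_domain.index(int(x))])
    return probs, flagged


@dataclass
class JointScoreDistribution:
    """Joint probability ``Q[a, b]`` of a pair of item scores."""

    item_a: ItemRef
    item_b: ItemRef
    domain_a: tuple[int, ...]
    domain_b: tuple[int, ...]
    counts: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if (self.Q < 0).any():
            raise ValueError("negative joint probabilities")
        if abs(self.Q.sum() - 1.0) > 1e-9:
            raise ValueError("joint distribution must sum to 1")

    def marginal_a(self) -> np.ndarray:
        return self.Q.sum(axis=1)

    def marginal_b(self) -> np.ndarray:
        return self.Q.sum(axis=0)

    def condition_on_b(self, b: int) -> np.ndarray:
        """``Pr(A | B = b)``; raises if that column has zero mass."""
        j = self.domain_b.index(int(b))
        col = self.Q[:, j]
        if col.sum() <= 0:
            raise EstimationError(f"no mass at B={b}; cannot condition")
        return col / col.sum()

    def to_dict(self) -> dict:
        return {
            "item_a": list(self.item_a),
            "item_b": list(self.item_b),
            "domain_a": list(self.domain_a),
            "domain_b": list(self.domain_b),
            "counts": self.counts.tolist(),
            "Q": self.Q.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointScoreDistribution":
        return cls(
            item_a=ItemRef(*d["item_a"]),
            item_b=ItemRef(*d["item_b"]),
            domain_a=tuple(d["domain_a"]),
            domain_b=tuple(d["domain_b"]),
            counts=np.asarray(d["counts"]),
            Q=np.asarray(d["Q"], dtype=float),
        )


def estimate_joint(table: ScoreTable, item_a: ItemRef, item_b: ItemRef) -> JointScoreDistribution:
    """Joint distribution of two items over all pairings, grand-total normalized."""
    a_item = _item(item_a, table.instruments)
    b_item = _item(item_b, table.instruments)
    pairs = _pairings(table, item_a, item_b)
    if pairs.empty:
        raise EstimationError(f"no pairings between {item_a} and {item_b}")
    counts = np.zeros((a_item.n_levels, b_item.n_levels))
    np.add.at(
        counts,
        (
            pairs["x"].to_numpy(int) - a_item.lo,
            pairs["y"].to_numpy(int) - b_item.lo,
        ),
        1,
    )
    return JointScoreDistribution(
        item_a=item_a,
        item_b=item_b,
        domain_a=tuple(a_item.domain),
        domain_b=tuple(b_item.domain),
        counts=counts.astype(int),
        Q=counts / counts.sum(),
    )


class MapDiagnostics(NamedTuple):
    """How close a map is to a clean crosswalk.

    ``bijectivity_fraction`` is the share of source rows whose most likely
    target equals the source value; ``bias`` is the mean of
    (target - source) over all pairings (negative = the target instrument
    underscores relative to the source).
    """

    bijectivity_fraction: float
    bias: float


def map_diagnostics(smap: StochasticMap) -> MapDiagnostics:
    src = np.asarray(smap.source_domain)
    tgt = np.asarray(smap.target_domain)
    argmax_vals = tgt[np.argmax(smap.P, axis=1)]
    bij = float(np.mean(argmax_vals == src))
    total = smap.counts.sum()
    if total > 0:
        diff = tgt[None, :] - src[:, None]
        bias = float((smap.counts * diff).sum() / total)
    else:  # pragma: no cover - estimation already forbids this
        bias = float("nan")
    return MapDiagnostics(bijectivity_fraction=bij, bias=bias)


@dataclass
class ClusterScoreMap:
    """QoL-cluster <-> target-total crosswalk.

    ``cluster_stats`` holds the mean/sd of the target instrument's total per
    QoL cluster (clusters are ordered by severity, so a monotone map has
    non-decreasing means).  ``level_stats`` goes the other way: the target
    total, normalized to [0, 1], is cut into four quartile bands ("levels"
    1..4) and each level carries the mean/sd of the QoL total, from which
    QoL totals can be synthesized by normal sampling.
    """

    target_instrument: str
    cluster_stats: pd.DataFrame  # index: cluster 1..k; columns mean, sd, n
    level_edges: np.ndarray  # 3 interior quantile edges on the normalized target total
    level_stats: pd.DataFrame  # index: level 1..4; columns mean, sd, n
    qol_total_max: int
    target_total_max: int
    monotone: bool
    warnings: list[str] = field(default_factory=list)

    def level_of(self, normalized_total: float | np.ndarray) -> np.ndarray:
        """Map normalized target totals to levels 1..4 by the stored quartile edges."""
        return np.searchsorted(self.level_edges, np.asarray(normalized_total, dtype=float), side="right") + 1

    def to_dict(self) -> dict:
        return {
            "target_instrument": self.target_instrument,
            "cluster_stats": {
                str(k): {c: float(v) for c, v in row.items()}
                for k, row in self.cluster_stats.iterrows()
            },
            "level_edges": [float(e) for e in self.level_edges],
            "level_stats": {
                str(k): {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
                for k, row in self.level_stats.iterrows()
            },
            "qol_total_max": self.qol_total_max,
            "target_total_max": self.target_total_max,
            "monotone": self.monotone,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterScoreMap":
        cs = pd.DataFrame.from_dict(d["cluster_stats"], orient="index")
        cs.index = cs.index.astype(int).rename("cluster")
        ls = pd.DataFrame.from_dict(d["level_stats"], orient="index")
        ls.index = ls.index.astype(int).rename("level")
        return cls(
            target_instrument=d["target_instrument"],
            cluster_stats=cs.sort_index(),
            level_edges=np.asarray(d["level_edges"], dtype=float),
            level_stats=ls.sort_index(),
            qol_total_max=int(d["qol_total_max"]),
            target_total_max=int(d["target_total_max"]),
            monotone=bool(d["monotone"]),
            warnings=list(d.get("warnings", [])),
        )


def fit_cluster_score_map(
    qol_model: "QoLClusterModel",
    table: ScoreTable,
    target_instrument: str = "MG-ADL",
) -> ClusterScoreMap:
    """Fit the two-way map between QoL fatigue clusters and a target total.

    Patient-visits carrying both a QoL cluster assignment and a complete
    target total are paired.  Per cluster the target total's mean/sd is
    computed; per quartile level of the normalized target total the QoL
    total's mean/sd is computed.
    """
    target = get_instrument(target_instrument, table.instruments)
    qol = get_instrument("MG-QOL15", table.instruments)
    totals = table.totals(target_instrument, "require_complete").dropna()
    qol_totals = table.totals("MG-QOL15", "require_complete").dropna()
    # collapse replicate raters to one assignment per patient-visit
    adf = qol_model.assignments.rename("cluster").reset_index()
    assign = adf.groupby(["patient_id", "visit_month"], sort=True)["cluster"].agg(
        lambda s: int(s.mode().iloc[0])
    )
    joined = (
        pd.DataFrame({"cluster": assign})
        .join(totals.rename("target_total"), how="inner")
        .join(qol_totals.rename("qol_total"), how="inner")
    )
    joined = joined.dropna(subset=["target_total"])
    if joined.empty:
        raise EstimationError(
            f"no patient-visits with both a QoL cluster and a complete {target_instrument} total"
        )
    warn: list[str] = []
    stats = joined.groupby("cluster")["target_total"].agg(["mean", "std", "count"])
    stats = stats.rename(columns={"std": "sd", "count": "n"})
    stats["sd"] = stats["sd"].fillna(0.0)
    stats = stats.reindex(range(1, qol_model.k + 1)).astype(float)
    stats.index.name = "cluster"
    if stats["n"].isna().any():
        warn.append("some clusters have no paired target totals")
    if (stats["n"].fillna(0) < 2).any():
        warn.append("cluster(s) with fewer than 2 paired visits: sd unreliable")
    norm = joined["target_total"] / target.total_max
    edges = np.quantile(norm, [0.25, 0.5, 0.75])
    levels = np.searchsorted(edges, norm.to_numpy(), side="right") + 1
    lv = joined.assign(level=levels).dropna(subset=["qol_total"])
    level_stats = (
        lv.groupby("level")["qol_total"].agg(["mean", "std", "count"])
        .rename(columns={"std": "sd", "count": "n"})
        .reindex([1, 2, 3, 4])
        .astype(float)
    )
    level_stats.index.name = "level"
    level_stats["sd"] = level_stats["sd"].where(level_stats["n"].notna(), np.nan).fillna(0.0)
    level_stats.loc[level_stats["n"].isna(), "sd"] = np.nan
    if level_stats["mean"].isna().any():
        warn.append("empty target level band(s); QoL sampling undefined there")
    means = stats["mean"].dropna().to_numpy()
    monotone = bool(np.all(np.diff(means) >= -1e-9))
    return ClusterScoreMap(
        target_instrument=target_instrument,
        cluster_stats=stats,
        level_edges=edges,
        level_stats=level_stats,
        qol_total_max=qol.total_max,
        target_total_max=target.total_max,
        monotone=monotone,
        warnings=warn,
    )


def sample_qol_from_level(
    cs_map: ClusterScoreMap,
    level: int,
    seed: int | None = None,
    size: int | None = None,
    rng: np.random.Generator | None = None,
) -> int | np.ndarray:
    """Draw integer QoL totals for a target level, ``Normal(mu, sigma)`` clipped to range."""
    if level not in (1, 2, 3, 4):
        raise ValueError(f"level must be 1..4, got {level}")
    row = cs_map.level_stats.loc[level]
    if pd.isna(row["mean"]):
        raise EstimationError(f"level {level} has no fitted mean")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = 1 if size is None else int(size)
    draws = rng.normal(row["mean"], row["sd"], size=n)
    draws = np.clip(np.rint(draws), 0, cs_map.qol_total_max).astype(int)
    return int(draws[0]) if size is None else draws
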