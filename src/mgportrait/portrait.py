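"""Probability-based score portraits.

A *score portrait* replaces the single number per item by a probability
distribution over the item's domain:

* an observed score is a point mass;
* replicate rater scores become a weighted histogram (``rater_aggregated``);
* a missing item with an observed, correlated partner on another
  instrument is filled with the partner-conditioned distribution — from a
  joint two-item distribution when one is available (``imputed_joint``),
  otherwise from the best-supported pairwise stochastic map
  (``imputed_map``);
* anything else falls back to the item's pooled empirical marginal
  (``imputed_marginal``).

Instrument totals are propagated as full distributions by discrete
convolution of the per-item distributions, assuming conditional
independence across items given the observed information — an explicit
approximation, since only pairwise maps are estimated.  Totals are
normalized by the instrument maximum so every instrument lives on [0, 1],
which makes the weighted composite alpha*MG-ADL + beta*QMG + gamma*QoL
(alpha + beta + gamma = 1) well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .maps import ItemRef, JointScoreDistribution, StochasticMap, impute_item
from .schema import Instrument, ScoreTable, get_instrument

__all__ = [
    "PortraitEntry",
    "TotalDistribution",
    "ScorePortrait",
    "CompositeWeights",
    "CompositeDistribution",
    "PortraitError",
    "aggregate_raters",
    "assemble_portrait",
    "assemble_all_portraits",
    "empirical_marginals",
    "composite_score",
]

PROVENANCES = (
    "observed",
    "rater_aggregated",
    "imputed_joint",
    "imputed_map",
    "imputed_marginal",
)


class PortraitError(ValueError):
    """Portrait cannot be assembled (e.g. nothing observed at the visit)."""


def aggregate_raters(
    values: Sequence[int],
    weights: Sequence[float] | None = None,
    n_levels: int = 4,
    lo: int = 0,
) -> np.ndarray:
    """Weighted histogram of replicate rater scores, normalized to 1.

    Equal weights by default; unequal weights let one evaluator be trusted
    more when objective grounds exist.
    """
    vals = list(values)
    if not vals:
        raise ValueError("no rater values to aggregate")
    if weights is None:
        weights = [1.0] * len(vals)
    w = np.asarray(list(weights), dtype=float)
    if len(w) != len(vals):
        raise ValueError("weights must match values in length")
    if (w < 0).any():
        raise ValueError("negative rater weight")
    if w.sum() <= 0:
        raise ValueError("rater weights must have positive sum")
    probs = np.zeros(n_levels)
    for v, wi in zip(vals, w):
        i = int(v) - lo
        if not 0 <= i < n_levels:
            raise ValueError(f"rater value {v} outside domain [{lo}..{lo + n_levels - 1}]")
        probs[i] += wi
    return probs / probs.sum()


@dataclass
class PortraitEntry:
    """Distribution over one item's domain with provenance."""

    probs: np.ndarray
    provenance: str
    fallback: bool = False  # True when an imputed_map row was marginal-filled

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("entry probabilities must be non-negative and sum to 1")

    @property
    def expectation(self) -> float:
        return float(np.dot(np.arange(len(self.probs)), self.probs))


@dataclass
class TotalDistribution:
    """Distribution of an instrument total on the integer support 0..total_max."""

    probs: np.ndarray  # length total_max + 1
    total_max: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.total_max + 1:
            raise ValueError("support length must be total_max + 1")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("total distribution must be normalized")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.total_max + 1)

    @property
    def normalized_support(self) -> np.ndarray:
        return self.support / self.total_max

    @property
    def expectation(self) -> float:
        return float(np.dot(self.support, self.probs))

    @property
    def normalized_expectation(self) -> float:
        return self.expectation / self.total_max


@dataclass
class ScorePortrait:
    """Per patient-visit: a distribution per item plus total distributions."""

    patient_id: str
    visit_month: float
    entries: dict[ItemRef, PortraitEntry]
    totals: dict[str, TotalDistribution]

    def expected_total(self, instrument: str, normalized: bool = True) -> float:
        t = self.totals[instrument]
        return t.normalized_expectation if normalized else t.expectation

    def provenance_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries.values():
            out[e.provenance] = out.get(e.provenance, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "visit_month": self.visit_month,
            "entries": {
                f"{ref.instrument}/{ref.item_id}": {
                    "probs": e.probs.tolist(),
                    "provenance": e.provenance,
                    "fallback": e.fallback,
                }
                for ref, e in self.entries.items()
            },
            "totals": {
                name: {"probs": t.probs.tolist(), "total_max": t.total_max}
                for name, t in self.totals.items()
            },
        }


def empirical_marginals(table: ScoreTable, instruments: Sequence[str]) -> dict[ItemRef, np.ndarray]:
    """Pooled empirical distribution of each item over all observed records.

    Items never observed anywhere get a uniform distribution.
    """
    out: dict[ItemRef, np.ndarray] = {}
    obs = table.observed()
    for name in instruments:
        ins = table.instrument(name)
        sub = obs[obs["instrument"] == name]
        for item in ins.items:
            vals = sub.loc[sub["item_id"] == item.item_id, "value"].to_numpy(int)
            counts = np.bincount(vals - item.lo, minlength=item.n_levels).astype(float)
            if counts.sum() == 0:
                out[ItemRef(name, item.item_id)] = np.full(item.n_levels, 1.0 / item.n_levels)
            else:
                out[ItemRef(name, item.item_id)] = counts / counts.sum()
    return out


def _convolve_total(entries: Iterable[PortraitEntry], instrument: Instrument) -> TotalDistribution:
    dist = np.array([1.0])
    for e in entries:
        dist = np.convolve(dist, e.probs)
    # item domains start at 0, so the convolution support is 0..total_max
    probs = np.zeros(instrument.total_max + 1)
    probs[: len(dist)] = dist
    probs /= probs.sum()
    return TotalDistribution(probs=probs, total_max=instrument.total_max)


def _observed_lookup(table: ScoreTable, patient_id: str, visit_month: float) -> dict:
    sub = table.observed()
    sub = sub[
        (sub["patient_id"] == str(patient_id))
        & (sub["visit_month"] == float(visit_month))
    ]
    lookup: dict[ItemRef, list[int]] = {}
    for _, row in sub.iterrows():
        lookup.setdefault(ItemRef(row["instrument"], row["item_id"]), []).append(
            int(row["value"])
        )
    return lookup


def assemble_portrait(
    table: ScoreTable,
    patient_id: str,
    visit_month: float,
    maps: Sequence[StochasticMap] = (),
    joints: Sequence[JointScoreDistribution] = (),
    marginals: Mapping[ItemRef, np.ndarray] | None = None,
    instruments: Sequence[str] | None = None,
    rater_weights: Mapping[str, Sequence[float]] | None = None,
    _observed: Mapping[ItemRef, list[int]] | None = None,
) -> ScorePortrait:
    """Assemble the probability portrait of one patient-visit.

    Fill priority per item: observed (or rater-aggregated when replicated)
    > joint-conditioned > best-supported pairwise map > pooled marginal.
    ``marginals`` defaults to the table's pooled empirical marginals.
    """
    if instruments is None:
        instruments = ("MG-ADL", "QMG", "MG-QOL15")
    observed = dict(_observed) if _observed is not None else _observed_lookup(
        table, patient_id, visit_month
    )
    if not observed:
        raise PortraitError(
            f"nothing observed for patient {patient_id!r} at month {visit_month}"
        )
    if marginals is None:
        marginals = empirical_marginals(table, instruments)

    entries: dict[ItemRef, PortraitEntry] = {}
    for name in instruments:
        ins = get_instrument(name, table.instruments)
        for item in ins.items:
            ref = ItemRef(name, item.item_id)
            if ref in observed:
                vals = observed[ref]
                if len(vals) == 1:
                    probs = np.zeros(item.n_levels)
                    probs[vals[0] - item.lo] = 1.0
                    entries[ref] = PortraitEntry(probs, "observed")
                else:
                    w = rater_weights.get(f"{name}/{item.item_id}") if rater_weights else None
                    probs = aggregate_raters(vals, w, n_levels=item.n_levels, lo=item.lo)
                    entries[ref] = PortraitEntry(probs, "rater_aggregated")
                continue
            # joint-conditioned imputation on all observed partners
            cond_dists: list[np.ndarray] = []
            for joint in joints:
                if joint.item_a == ref and joint.item_b in observed:
                    b = int(np.rint(np.mean(observed[joint.item_b])))
                    cond_dists.append(joint.condition_on_b(b))
                elif joint.item_b == ref and joint.item_a in observed:
                    a = int(np.rint(np.mean(observed[joint.item_a])))
                    col = joint.Q[joint.domain_a.index(a), :]
                    if col.sum() > 0:
                        cond_dists.append(col / col.sum())
            if cond_dists:
                # combine several conditionals by normalized product
                probs = np.ones(item.n_levels)
                for d in cond_dists:
                    probs *= d
                if probs.sum() > 0:
                    entries[ref] = PortraitEntry(probs / probs.sum(), "imputed_joint")
                    continue
            # best single-partner stochastic map, chosen by row support
            best: tuple[int, np.ndarray, bool] | None = None
            for smap in maps:
                if smap.target != ref or smap.source not in observed:
                    continue
                x = int(np.rint(np.mean(observed[smap.source])))
                support = int(smap.row_support[smap.source_domain.index(x)])
                probs, flagged = impute_item(smap, x)
                if best is None or support > best[0]:
                    best = (support, probs, flagged)
            if best is not None:
                entries[ref] = PortraitEntry(best[1], "imputed_map", fallback=best[2])
                continue
            if ref not in marginals:
                raise PortraitError(f"no marginal available for {ref}")
            entries[ref] = PortraitEntry(np.asarray(marginals[ref]), "imputed_marginal")

    totals = {
        name: _convolve_total(
            (entries[ItemRef(name, it.item_id)] for it in get_instrument(name, table.instruments).items),
            get_instrument(name, table.instruments),
        )
        for name in instruments
    }
    return ScorePortrait(
        patient_id=str(patient_id),
        visit_month=float(visit_month),
        entries=entries,
        totals=totals,
    )


def assemble_all_portraits(
    table: ScoreTable,
    maps: Sequence[StochasticMap] = (),
    joints: Sequence[JointScoreDistribution] = (),
    instruments: Sequence[str] | None = None,
) -> dict[tuple[str, float], ScorePortrait]:
    """Portraits for every patient-visit with at least one observed instrument."""
    if instruments is None:
        instruments = ("MG-ADL", "QMG", "MG-QOL15")
    marginals = empirical_marginals(table, instruments)
    obs = table.observed()
    grouped: dict[tuple[str, float], dict[ItemRef, list[int]]] = {}
    for (pid, month, ins_name, item_id), sub in obs.groupby(
        ["patient_id", "visit_month", "instrument", "item_id"], sort=True
    ):
        grouped.setdefault((pid, month), {})[ItemRef(ins_name, item_id)] = [
            int(v) for v in sub["value"]
        ]
    out: dict[tuple[str, float], ScorePortrait] = {}
    for (pid, month), observed_items in grouped.items():
        out[(pid, month)] = assemble_portrait(
            table,
            pid,
            month,
            maps=maps,
            joints=joints,
            marginals=marginals,
            instruments=instruments,
            _observed=observed_items,
        )
    return out


@dataclass(frozen=True)
class CompositeWeights:
    """Non-negative weights (alpha, beta, gamma) summing to 1 for
    MG-ADL, QMG and QoL respectively."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name, v in zip(("alpha", "beta", "gamma"), (self.alpha, self.beta, self.gamma)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-12:
            raise ValueError("alpha + beta + gamma must equal 1")


@dataclass
class CompositeDistribution:
    """Discrete distribution of the weighted composite on [0, 1]."""

    values: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("composite distribution must be normalized")

    @property
    def expectation(self) -> float:
        return float(np.dot(self.values, self.probs))


_COMPOSITE_ORDER = ("MG-ADL", "QMG", "MG-QOL15")


def composite_score(
    portrait: ScorePortrait, weights: CompositeWeights
) -> CompositeDistribution:
    """Distribution of alpha*ADL + beta*QMG + gamma*QoL on normalized totals.

    Exact enumeration over the product support of the three total
    distributions (the supports are small integers, so this is cheap);
    values are de-duplicated on a fine grid so the expectation is exactly
    the weighted sum of the three expectations.
    """
    missing = [n for n in _COMPOSITE_ORDER if n not in portrait.totals]
    if missing:
        raise PortraitError(f"composite needs totals for {missing}")
    dists = [portrait.totals[n] for n in _COMPOSITE_ORDER]
    w = (weights.alpha, weights.beta, weights.gamma)
    vals = (
        w[0] * dists[0].normalized_support[:, None, None]
        + w[1] * dists[1].normalized_support[None, :, None]
        + w[2] * dists[2].normalized_support[None, None, :]
    )
    probs = (
        dists[0].probs[:, None, None]
        * dists[1].probs[None, :, None]
        * dists[2].probs[None, None, :]
    )
    flat_vals = np.round(vals.ravel(), 12)
    flat_probs = probs.ravel()
    keep = flat_probs > 0
    uniq, inv = np.unique(flat_vals[keep], return_inverse=True)
    agg = np.zeros(len(uniq))
    np.add.at(agg, inv, flat_probs[keep])
    return CompositeDistribution(values=uniq, probs=agg / agg.sum())
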