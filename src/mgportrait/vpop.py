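"""Monte-Carlo virtual populations from score portraits.

Each source patient is replicated ``scale`` times.  Per replicate and
visit, observed item scores are perturbed with Gaussian measurement noise
and re-discretized, imputed items are drawn from their portrait
distributions, and the quality-of-life total is synthesized from the
replicate's MG-ADL level band through the fitted cluster-score map (QoL
inherits the patient-reported dynamics, because both are patient-reported
outcomes).  Covariates are copied unchanged from the source patient, and a
lineage table records which virtual patient came from which source.

The ``noise_sd`` parameter is the standard deviation of the *realized
integer* perturbation: because scores are ordinal the noisy value is
rounded (half away from zero) back to the domain, which inflates the raw
Gaussian spread by the rounding variance, so the internal continuous sigma
is shrunk by Sheppard's correction (sigma^2 = noise_sd^2 - 1/12).  Away
from the clipping boundaries the emitted perturbations then have standard
deviation ``noise_sd`` as specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maps import ClusterScoreMap, ItemRef
from .portrait import ScorePortrait
from .schema import COLUMNS, Instrument, ScoreTable, get_instrument

__all__ = ["VpopConfig", "VirtualCohort", "generate_vpop", "vpop_summary"]


@dataclass
class VpopConfig:
    """Monte-Carlo settings for virtual-population generation."""

    scale: int = 10
    noise_sd: float = 1.0
    seed: int = 0
    #: instruments whose item scores are replicated (QoL is synthesized as a total)
    instruments: tuple[str, ...] = ("MG-ADL", "QMG")
    #: source patients need at least this many visits where every replicated
    #: instrument was actually observed
    min_source_visits: int = 2

    def validate(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.min_source_visits < 1:
            raise ValueError("min_source_visits must be >= 1")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _effective_sigma(noise_sd: float) -> float:
    # Sheppard's correction: rounding to the integer lattice adds ~1/12 variance
    return float(np.sqrt(max(noise_sd**2 - 1.0 / 12.0, 0.0))) if noise_sd > 0 else 0.0


@dataclass
class VirtualCohort:
    """Replicated integer score trajectories plus lineage and covariates."""

    scores: ScoreTable  # item scores for the replicated instruments
    qol_totals: pd.DataFrame  # virtual_id, visit_month, qol_total
    lineage: pd.DataFrame  # virtual_id, source_patient_id, replicate_index
    covariates: pd.DataFrame | None
    scale: int
    noise_sd: float
    seed: int
    n_source_patients: int
    n_dropped_sources: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.lineage)


_OBSERVED_PROV = ("observed", "rater_aggregated")


def generate_vpop(
    portraits: Mapping[tuple[str, float], ScorePortrait],
    cluster_score_map: ClusterScoreMap | None,
    config: VpopConfig,
    covariates: pd.DataFrame | None = None,
    instrument_defs: Sequence[Instrument] | None = None,
) -> VirtualCohort:
    """Generate ``scale`` virtual replicates of every eligible source patient.

    Per visit: items with provenance ``observed`` keep their value, items
    with ``rater_aggregated`` are drawn from the rater histogram, and both
    get additive measurement noise; imputed items are drawn from their
    portrait distributions without extra noise.  When ``cluster_score_map``
    is given, a QoL total is synthesized per visit from the replicate's
    MG-ADL quartile level.  Randomness is fully seeded with an independent
    substream per (source patient, replicate).
    """
    config.validate()
    if not portraits:
        raise ValueError("empty portrait set")
    by_patient: dict[str, dict[float, ScorePortrait]] = {}
    for (pid, month), p in sorted(portraits.items()):
        by_patient.setdefault(pid, {})[month] = p

    ins_objs = [get_instrument(n, instrument_defs) for n in config.instruments]
    sigma = _effective_sigma(config.noise_sd)

    eligible: list[str] = []
    dropped = 0
    for pid, visits in by_patient.items():
        n_ok = 0
        for month, p in visits.items():
            ok = all(
                any(
                    p.entries[ItemRef(ins.name, it.item_id)].provenance in _OBSERVED_PROV
                    for it in ins.items
                )
                for ins in ins_objs
            )
            n_ok += int(ok)
        if n_ok >= config.min_source_visits:
            eligible.append(pid)
        else:
            dropped += 1

    score_frames: list[pd.DataFrame] = []
    qol_rows: list[pd.DataFrame] = []
    lineage_rows: list[tuple[str, str, int]] = []

    for src_idx, pid in enumerate(eligible):
        visits = by_patient[pid]
        months = np.array(sorted(visits))
        V = len(months)
        # flatten (instrument, item, visit) entries once per source patient
        refs: list[ItemRef] = []
        ins_names: list[str] = []
        item_ids: list[str] = []
        month_col: list[float] = []
        lo_list: list[int] = []
        hi_list: list[int] = []
        prob_rows: list[np.ndarray] = []
        prov_obs: list[bool] = []  # gets measurement noise
        prov_point: list[bool] = []  # single observed value: keep as-is before noise
        max_levels = max(it.n_levels for ins in ins_objs for it in ins.items)
        for ins in ins_objs:
            for it in ins.items:
                ref = ItemRef(ins.name, it.item_id)
                for m in months:
                    e = visits[m].entries[ref]
                    refs.append(ref)
                    ins_names.append(ins.name)
                    item_ids.append(it.item_id)
                    month_col.append(float(m))
                    lo_list.append(it.lo)
                    hi_list.append(it.hi)
                    padded = np.zeros(max_levels)
                    padded[: len(e.probs)] = e.probs
                    prob_rows.append(padded)
                    prov_obs.append(e.provenance in _OBSERVED_PROV)
                    prov_point.append(e.provenance == "observed")
        E = len(refs)
        cum = np.cumsum(np.stack(prob_rows), axis=1)
        lo = np.array(lo_list)
        hi = np.array(hi_list)
        obs_mask = np.array(prov_obs)
        point_mask = np.array(prov_point)
        point_val = np.array(
            [
                int(np.argmax(p[: h - l + 1])) + l if pt else 0
                for p, l, h, pt in zip(prob_rows, lo, hi, prov_point)
            ]
        )
        ins_arr = np.array(ins_names)
        item_arr = np.array(item_ids)
        month_arr = np.array(month_col)
        adl_sel = ins_arr == "MG-ADL"

        for rep in range(config.scale):
            rng = np.random.default_rng([config.seed, src_idx, rep])
            u = rng.random(E)
            drawn = (u[:, None] > cum).sum(axis=1) + lo
            base = np.where(point_mask, point_val, drawn).astype(float)
            if config.noise_sd > 0:
                noise = rng.normal(0.0, sigma, E)
                noisy = np.where(obs_mask, base + noise, base)
            else:
                noisy = base
            vals = np.clip(_round_half_away(noisy), lo, hi).astype(int)
            vid = f"{pid}-r{rep + 1:02d}"
            lineage_rows.append((vid, pid, rep))
            score_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": vid,
                        "visit_month": month_arr,
                        "instrument": ins_arr,
                        "item_id": item_arr,
                        "rater_id": None,
                        "value": vals.astype(float),
                    }
                )
            )
            if cluster_score_map is not None and adl_sel.any():
                adl_max = get_instrument("MG-ADL", instrument_defs).total_max
                adl_tot = np.zeros(V)
                for vi, m in enumerate(months):
                    adl_tot[vi] = vals[adl_sel & (month_arr == m)].sum()
                levels = cluster_score_map.level_of(adl_tot / adl_max)
                mu = cluster_score_map.level_stats["mean"].reindex(levels).to_numpy()
                sd = cluster_score_map.level_stats["sd"].reindex(levels).to_numpy()
                q = np.clip(
                    np.rint(rng.normal(mu, sd)), 0, cluster_score_map.qol_total_max
                ).astype(int)
                qol_rows.append(
                    pd.DataFrame(
                        {"virtual_id": vid, "visit_month": months, "qol_total": q}
                    )
                )

    if not score_frames:
        raise ValueError(
            "no source patient satisfies the completeness filter "
            f"(min_source_visits={config.min_source_visits})"
        )
    scores = ScoreTable(
        pd.concat(score_frames, ignore_index=True)[COLUMNS],
        instruments=instrument_defs,
        validate=False,  # values are clipped into domain by construction
    )
    lineage = pd.DataFrame(
        lineage_rows, columns=["virtual_id", "source_patient_id", "replicate_index"]
    )
    cov = None
    if covariates is not None:
        cov = lineage.merge(
            covariates, left_on="source_patient_id", right_on="patient_id", how="left"
        ).drop(columns=["patient_id"])
    cohort = VirtualCohort(
        scores=scores,
        qol_totals=(
            pd.concat(qol_rows, ignore_index=True)
            if qol_rows
            else pd.DataFrame(columns=["virtual_id", "visit_month", "qol_total"])
        ),
        lineage=lineage,
        covariates=cov,
        scale=config.scale,
        noise_sd=config.noise_sd,
        seed=config.seed,
        n_source_patients=len(eligible),
        n_dropped_sources=dropped,
    )
    assert cohort.n_patients == config.scale * len(eligible)
    return cohort


def vpop_summary(cohort: VirtualCohort) -> pd.DataFrame:
    """Mean/sd of instrument totals per (instrument, visit) over virtual patients."""
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    rows = []
    df = cohort.scores.df
    totals = (
        df.groupby(["instrument", "patient_id", "visit_month"])["value"]
        .sum()
        .reset_index()
    )
    for (ins, month), sub in totals.groupby(["instrument", "visit_month"]):
        rows.append(
            {
                "instrument": ins,
                "visit_month": month,
                "mean": sub["value"].mean(),
                "sd": sub["value"].std(ddof=0),
                "n": len(sub),
            }
        )
    if len(cohort.qol_totals):
        for month, sub in cohort.qol_totals.groupby("visit_month"):
            rows.append(
                {
                    "instrument": "MG-QOL15_total",
                    "visit_month": month,
                    "mean": sub["qol_total"].mean(),
                    "sd": sub["qol_total"].std(ddof=0),
                    "n": len(sub),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["instrument", "visit_month"])
        .reset_index(drop=True)
    )
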