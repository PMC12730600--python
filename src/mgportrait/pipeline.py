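"""One-command orchestration: simulate -> structure -> maps -> portraits ->
virtual population -> trajectories, with a reproducibility manifest.

Every stage writes plain CSV/JSON artifacts into its own subdirectory of
the output directory and can be re-run individually against a prior run's
artifacts.  All randomness flows from the single configured seed through
named substreams, and no artifact embeds timestamps, so a repeated run
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import maps as maps_mod
from . import portrait as portrait_mod
from . import structure as structure_mod
from . import trajectory as trajectory_mod
from . import vpop as vpop_mod
from .maps import ClusterScoreMap, DEFAULT_CORRESPONDENCE, ItemRef, StochasticMap
from .schema import ScoreTable, read_scores, write_scores
from .synthetic import CohortConfig, CovariateParams, GroundTruth, generate_cohort

logger = logging.getLogger("mgportrait")

__all__ = ["RunConfig", "ConfigurationError", "validate_config", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class ConfigurationError(ValueError):
    """Aggregated, human-readable configuration problems."""


@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rho_threshold: float = 0.5
    alpha: float = 0.01
    qol_k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    correspondence: tuple[tuple[ItemRef, ItemRef], ...] = DEFAULT_CORRESPONDENCE
    pseudo_count: float = 0.0
    composite_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    vpop: vpop_mod.VpopConfig = field(default_factory=vpop_mod.VpopConfig)
    trajectory_k: int = 4
    output_dir: str = "results/run"
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        errors: list[str] = []
        try:
            self.cohort.validate()
        except ValueError as e:
            errors.append(f"cohort: {e}")
        try:
            self.vpop.validate()
        except ValueError as e:
            errors.append(f"vpop: {e}")
        if not 0 < self.rho_threshold <= 1:
            errors.append(f"rho_threshold must be in (0, 1], got {self.rho_threshold}")
        if not 0 < self.alpha <= 1:
            errors.append(f"alpha must be in (0, 1], got {self.alpha}")
        w = self.composite_weights
        if len(w) != 3 or any(x < 0 for x in w):
            errors.append("composite_weights must be three non-negative numbers")
        elif abs(sum(w) - 1.0) > 1e-9:
            errors.append(
                f"composite_weights must sum to 1 (alpha + beta + gamma = 1), got {sum(w):g}"
            )
        if self.trajectory_k < 2:
            errors.append("trajectory_k must be >= 2")
        ks = list(self.qol_k_range)
        if not ks or min(ks) < 2 or max(ks) > 8:
            errors.append(f"qol_k_range must lie within 2..8, got {ks}")
        return errors


_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortConfig)} - {"archetypes"}
_VPOP_KEYS = {f.name for f in dataclasses.fields(vpop_mod.VpopConfig)}
_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)} | {"n_patients", "seed"}


def _build_config(raw: Mapping[str, Any]) -> RunConfig:
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    cohort_raw = dict(raw.get("cohort", {}))
    # convenience shortcuts at top level
    if "n_patients" in raw:
        cohort_raw.setdefault("n_patients", raw["n_patients"])
    if "seed" in raw:
        cohort_raw.setdefault("seed", raw["seed"])
    unknown_c = set(cohort_raw) - _COHORT_KEYS
    if unknown_c:
        errors.append(f"unknown cohort keys: {sorted(unknown_c)}")
    if "covariates" in cohort_raw:
        cohort_raw["covariates"] = CovariateParams(**cohort_raw["covariates"])
    for tup_key in ("visit_schedule", "instruments", "archetype_weights"):
        if tup_key in cohort_raw:
            cohort_raw[tup_key] = tuple(cohort_raw[tup_key])
    vpop_raw = dict(raw.get("vpop", {}))
    unknown_v = set(vpop_raw) - _VPOP_KEYS
    if unknown_v:
        errors.append(f"unknown vpop keys: {sorted(unknown_v)}")
    if "instruments" in vpop_raw:
        vpop_raw["instruments"] = tuple(vpop_raw["instruments"])
    if errors:
        raise ConfigurationError("; ".join(errors))
    cohort = CohortConfig(**{k: v for k, v in cohort_raw.items() if k in _COHORT_KEYS})
    vpop_cfg = vpop_mod.VpopConfig(**vpop_raw)
    if "seed" in raw and "seed" not in vpop_raw:
        vpop_cfg.seed = int(raw["seed"])
    kwargs: dict[str, Any] = {}
    for key in ("rho_threshold", "alpha", "pseudo_count", "trajectory_k", "output_dir", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    if "qol_k_range" in raw:
        kwargs["qol_k_range"] = tuple(int(k) for k in raw["qol_k_range"])
    if "composite_weights" in raw:
        kwargs["composite_weights"] = tuple(float(x) for x in raw["composite_weights"])
    if "correspondence" in raw:
        kwargs["correspondence"] = tuple(
            (ItemRef(*a), ItemRef(*b)) for a, b in raw["correspondence"]
        )
    cfg = RunConfig(cohort=cohort, vpop=vpop_cfg, **kwargs)
    errs = cfg.validate()
    if errs:
        raise ConfigurationError("; ".join(errs))
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{p}: config must be a mapping")
    return _build_config(raw)


def _config_echo(cfg: RunConfig) -> dict:
    def enc(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    echo = enc(cfg)
    # where the artifacts land does not affect their content; keeping the
    # path out of the echo makes runs into different directories comparable
    echo.pop("output_dir", None)
    return echo


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir: Path):
    d = outdir / "cohort"
    d.mkdir(parents=True, exist_ok=True)
    table, covariates, truth = generate_cohort(cfg.cohort)
    write_scores(table, d / "scores.csv")
    _write_csv(covariates, d / "covariates.csv")
    truth.to_json(d / "ground_truth.json")
    logger.info("simulate: %d score records, %d patients", len(table), cfg.cohort.n_patients)
    return table, covariates, truth


def stage_structure(cfg: RunConfig, outdir: Path, table: ScoreTable):
    d = outdir / "structure"
    d.mkdir(parents=True, exist_ok=True)
    groupings = {}
    for ins_name in cfg.cohort.instruments:
        corr = structure_mod.correlation_matrix(table, ins_name)
        grouping = structure_mod.regroup_strong_pairs(
            corr, rho_threshold=cfg.rho_threshold, alpha=cfg.alpha
        )
        groupings[ins_name] = grouping
        safe = ins_name.replace("/", "_")
        _write_json(d / f"correlation_{safe}.json", corr.to_dict())
        _write_json(d / f"grouping_{safe}.json", grouping.to_dict())
    qol_model = None
    if "MG-QOL15" in cfg.cohort.instruments:
        k = structure_mod.select_qol_k(
            table, cfg.qol_k_range, seed=cfg.cohort.seed
        )
        qol_model = structure_mod.cluster_qol(table, k, seed=cfg.cohort.seed)
        _write_json(d / "qol_clusters.json", qol_model.to_dict())
        logger.info("structure: QoL k=%d, mean silhouette %.3f", k, qol_model.mean_silhouette)
    return groupings, qol_model


def stage_maps(cfg: RunConfig, outdir: Path, table: ScoreTable, qol_model):
    d = outdir / "maps"
    d.mkdir(parents=True, exist_ok=True)
    fitted: list[StochasticMap] = []
    available = {
        (ins, item)
        for ins, item in table.observed()[["instrument", "item_id"]].drop_duplicates().itertuples(
            index=False
        )
    }
    for src, tgt in cfg.correspondence:
        if tuple(src) not in available or tuple(tgt) not in available:
            continue
        for a, b in ((src, tgt), (tgt, src)):
            smap = maps_mod.estimate_map(table, a, b, pseudo_count=cfg.pseudo_count)
            fitted.append(smap)
            name = f"map_{a.instrument}_{a.item_id}__{b.instrument}_{b.item_id}.json"
            _write_json(d / name.replace("/", "_"), smap.to_dict())
    cs_map = None
    if qol_model is not None and "MG-ADL" in cfg.cohort.instruments:
        cs_map = maps_mod.fit_cluster_score_map(qol_model, table, "MG-ADL")
        _write_json(d / "cluster_score_map.json", cs_map.to_dict())
    logger.info("maps: %d stochastic maps fitted", len(fitted))
    return fitted, cs_map


def stage_portraits(cfg: RunConfig, outdir: Path, table: ScoreTable, fitted_maps):
    d = outdir / "portraits"
    d.mkdir(parents=True, exist_ok=True)
    portraits = portrait_mod.assemble_all_portraits(
        table, maps=fitted_maps, instruments=cfg.cohort.instruments
    )
    weights = portrait_mod.CompositeWeights(*cfg.composite_weights)
    rows = []
    for (pid, month), p in sorted(portraits.items()):
        row: dict[str, Any] = {"patient_id": pid, "visit_month": month}
        for ins in cfg.cohort.instruments:
            row[f"expected_total_{ins}"] = p.expected_total(ins)
        if all(n in p.totals for n in ("MG-ADL", "QMG", "MG-QOL15")):
            row["composite_expectation"] = portrait_mod.composite_score(p, weights).expectation
        for prov, cnt in sorted(p.provenance_counts().items()):
            row[f"n_{prov}"] = cnt
        rows.append(row)
    summary = pd.DataFrame(rows).fillna(0)
    _write_csv(summary, d / "portraits_summary.csv")
    logger.info("portraits: %d patient-visits", len(portraits))
    return portraits


def stage_vpop(cfg: RunConfig, outdir: Path, portraits, cs_map, covariates):
    d = outdir / "vpop"
    d.mkdir(parents=True, exist_ok=True)
    cohort = vpop_mod.generate_vpop(portraits, cs_map, cfg.vpop, covariates=covariates)
    write_scores(cohort.scores, d / "scores.csv")
    _write_csv(cohort.qol_totals, d / "qol_totals.csv")
    _write_csv(cohort.lineage, d / "lineage.csv")
    _write_csv(vpop_mod.vpop_summary(cohort), d / "summary.csv")
    logger.info(
        "vpop: %d virtual patients from %d sources (scale %d)",
        cohort.n_patients,
        cohort.n_source_patients,
        cfg.vpop.scale,
    )
    return cohort

def stage_trajectories(cfg: RunConfig, outdir: Path, vcohort, covariates, truth: GroundTruth | None):
    d = outdir / "trajectories"
    d.mkdir(parents=True, exist_ok=True)
    instruments = list(cfg.vpop.instruments)
    if len(vcohort.qol_totals):
        instruments.append("MG-QOL15")
    matrix = trajectory_mod.build_trajectories(
        vcohort, instruments=instruments, schedule=cfg.cohort.visit_schedule
    )
    clustering = trajectory_mod.cluster_trajectories(
        matrix, k=cfg.trajectory_k, seed=cfg.vpop.seed
    )
    assignments = clustering.assignments.rename("cluster").reset_index()
    _write_csv(assignments, d / "assignments.csv")
    _write_csv(clustering.mean_trajectories.reset_index(), d / "mean_trajectories.csv")
    subgroups = None
    if covariates is not None:
        subgroups = trajectory_mod.summarize_subgroups(
            clustering, vcohort.lineage, covariates
        )
        _write_csv(subgroups.table, d / "subgroups.csv", index=True)
    ari = None
    if truth is not None:
        joined = assignments.merge(vcohort.lineage, on="virtual_id").merge(
            truth.archetype.rename("archetype").reset_index(),
            left_on="source_patient_id",
            right_on="patient_id",
        )
        ari = float(adjusted_rand_score(joined["archetype"], joined["cluster"]))
    logger.info(
        "trajectories: k=%d, mean silhouette %.3f, ARI vs planted %s",
        clustering.k,
        clustering.mean_silhouette,
        "n/a" if ari is None else f"{ari:.3f}",
    )
    return matrix, clustering, subgroups, ari


@dataclass
class StudyResult:
    """In-memory result of one synthetic study (no artifacts written)."""

    table: ScoreTable
    covariates: pd.DataFrame
    truth: GroundTruth
    qol_model: Any
    cluster_score_map: Any
    maps: list
    portraits: dict
    vcohort: Any
    matrix: Any
    clustering: Any
    subgroups: Any
    archetype_ari: float
    instrument_orders: dict[str, list[int]]


def run_synthetic_study(
    cohort_config: CohortConfig | None = None,
    vpop_config: vpop_mod.VpopConfig | None = None,
    qol_k: int = 4,
    trajectory_k: int = 4,
    seed: int | None = None,
) -> StudyResult:
    """Full simulate -> structure -> maps -> portraits -> vpop -> trajectories
    sequence in memory, returning every intermediate object plus the
    archetype-recovery ARI and per-instrument cluster rank orders."""
    cohort_config = cohort_config or CohortConfig()
    vpop_config = vpop_config or vpop_mod.VpopConfig()
    if seed is not None:
        cohort_config.seed = seed
        vpop_config.seed = seed
    table, covariates, truth = generate_cohort(cohort_config)
    qol_model = structure_mod.cluster_qol(table, qol_k, seed=cohort_config.seed)
    cs_map = maps_mod.fit_cluster_score_map(qol_model, table, "MG-ADL")
    fitted: list[StochasticMap] = []
    for src, tgt in DEFAULT_CORRESPONDENCE:
        for a, b in ((src, tgt), (tgt, src)):
            fitted.append(maps_mod.estimate_map(table, a, b))
    portraits = portrait_mod.assemble_all_portraits(
        table, maps=fitted, instruments=cohort_config.instruments
    )
    vcohort = vpop_mod.generate_vpop(portraits, cs_map, vpop_config, covariates=covariates)
    matrix = trajectory_mod.build_trajectories(
        vcohort, schedule=cohort_config.visit_schedule
    )
    clustering = trajectory_mod.cluster_trajectories(
        matrix, k=trajectory_k, seed=vpop_config.seed
    )
    subgroups = trajectory_mod.summarize_subgroups(
        clustering, vcohort.lineage, covariates
    )
    joined = (
        clustering.assignments.reset_index()
        .merge(vcohort.lineage, on="virtual_id")
        .merge(
            truth.archetype.rename("archetype").reset_index(),
            left_on="source_patient_id",
            right_on="patient_id",
        )
    )
    ari = float(adjusted_rand_score(joined["archetype"], joined["cluster"]))
    orders = trajectory_mod.instrument_rank_orders(matrix, clustering)
    return StudyResult(
        table=table,
        covariates=covariates,
        truth=truth,
        qol_model=qol_model,
        cluster_score_map=cs_map,
        maps=fitted,
        portraits=portraits,
        vcohort=vcohort,
        matrix=matrix,
        clustering=clustering,
        subgroups=subgroups,
        archetype_ari=ari,
        instrument_orders=orders,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order; returns the artifact directory.

    The manifest records the config echo, seed, per-stage record counts and
    the end-to-end archetype-recovery ARI, and suffices to re-run the
    identical pipeline.
    """
    errs = config.validate()
    if errs:
        raise ConfigurationError("; ".join(errs))
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _config_echo(config),
        "seed": config.cohort.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        table, covariates, truth = stage_simulate(config, outdir)
        manifest["stages"]["simulate"] = {
            "n_records": len(table),
            "n_patients": config.cohort.n_patients,
        }
        stage = "structure"
        groupings, qol_model = stage_structure(config, outdir, table)
        manifest["stages"]["structure"] = {
            "groupings": {k: [sorted(b) for b in g.groups] for k, g in groupings.items()},
            "qol_k": None if qol_model is None else qol_model.k,
            "qol_mean_silhouette": None
            if qol_model is None
            else round(qol_model.mean_silhouette, 6),
        }
        stage = "maps"
        fitted_maps, cs_map = stage_maps(config, outdir, table, qol_model)
        manifest["stages"]["maps"] = {
            "n_maps": len(fitted_maps),
            "cluster_score_map_monotone": None if cs_map is None else cs_map.monotone,
        }
        stage = "portraits"
        portraits = stage_portraits(config, outdir, table, fitted_maps)
        manifest["stages"]["portraits"] = {"n_patient_visits": len(portraits)}
        stage = "vpop"
        vcohort = stage_vpop(config, outdir, portraits, cs_map, covariates)
        manifest["stages"]["vpop"] = {
            "n_virtual_patients": vcohort.n_patients,
            "n_source_patients": vcohort.n_source_patients,
            "n_dropped_sources": vcohort.n_dropped_sources,
            "n_records": len(vcohort.scores),
        }
        stage = "trajectories"
        matrix, clustering, subgroups, ari = stage_trajectories(
            config, outdir, vcohort, covariates, truth
        )
        manifest["stages"]["trajectories"] = {
            "n_trajectories": matrix.X.shape[0],
            "n_dropped": matrix.n_dropped,
            "k": clustering.k,
            "mean_silhouette": round(clustering.mean_silhouette, 6),
            "cluster_sizes": {str(c): int(v) for c, v in clustering.sizes().items()},
            "archetype_recovery_ari": None if ari is None else round(ari, 6),
        }
    except Exception as e:
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        _write_json(outdir / "manifest.json", manifest)
        raise
    _write_json(outdir / "manifest.json", manifest)
    return outdir
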