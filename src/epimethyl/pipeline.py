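"""End-to-end pipeline orchestration.

A single configuration drives: simulate (optional) -> per-subject table
IO -> common-site intersection -> informative-site filter -> moderated
differential testing -> DML tracks and gene/category tables -> NMDS ->
adaptive LDA-panel search -> blinded-cohort voting -> metrics and ROC.
Every constant of the analysis (the 10-point filter, top 200 pool,
15-40 panel sizes, 8+8 training splits, 20 replicates, the 98%/90%
gates, the 10,000-evaluation reweight interval, 1 Mbp bins, 2 kb
promoters) lives in the config, never in stage logic.

A single master seed spawns one child seed per stage through
``numpy.random.SeedSequence``, so any stage can be rerun in isolation
and the whole pipeline is bit-reproducible; the manifest records every
artifact with the parameters and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diffmeth, ensemble, io, load, nmds
from .datamodel import Group, intersect_common_sites
from .simulate import (
    BlindedConfig,
    SimulationConfig,
    generate_blinded_cohort,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "FilterConfig",
    "DiffConfig",
    "NMDSConfig",
    "EnsembleConfig",
    "validate_config",
    "run_pipeline",
]

_STAGES = (
    "simulate",
    "blinded",
    "nmds",
    "search",
    "vote",
    "theoretical_roc",
)


@dataclass
class FilterConfig:
    threshold: float = 10.0  # percentage points, inclusive


@dataclass
class DiffConfig:
    fdr: float = 0.05
    top_k: int = 200
    p_method: str = "exact"


@dataclass
class NMDSConfig:
    metric: str = "euclidean"
    restarts: int = 4
    max_iter: int = 500
    tol: float = 1e-6


@dataclass
class EnsembleConfig:
    budget: int = 20_000
    sensitivity_gate: float = 0.98
    specificity_gate: float = 0.90
    replicates: int = 20
    train_per_group: int = 8
    panel_min: int = 15
    panel_max: int = 40
    reweight_interval: int = 10_000
    boost: float = 2.0
    ridge_lambda: float = 0.5
    max_good: int | None = None
    theoretical_bootstrap: int = 200


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "epimethyl_out"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    nmds: NMDSConfig = field(default_factory=NMDSConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = dict(data.pop("simulate", {}))
        blinded = BlindedConfig(**sim.pop("blinded", {})) if "blinded" in sim else BlindedConfig()
        return cls(
            seed=data.get("seed", 0),
            out_dir=data.get("out_dir", "epimethyl_out"),
            simulate=SimulationConfig(blinded=blinded, **sim),
            filter=FilterConfig(**data.get("filter", {})),
            diff=DiffConfig(**data.get("diff", {})),
            nmds=NMDSConfig(**data.get("nmds", {})),
            ensemble=EnsembleConfig(**data.get("ensemble", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        """Per-stage child seed derived from the master seed; stable
        across runs and independent across stages."""
        idx = _STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGES))[idx]
        return int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations (empty = valid); each names the
    offending key and the constraint."""
    v: list[str] = []
    if config.seed < 0:
        v.append("seed: must be a non-negative integer")
    if not 0.0 <= config.filter.threshold <= 100.0:
        v.append("filter.threshold: must be in [0, 100] percentage points")
    if not 0.0 < config.diff.fdr < 1.0:
        v.append("diff.fdr: must be in (0, 1)")
    if config.diff.top_k < 1:
        v.append("diff.top_k: must be >= 1")
    if config.diff.p_method not in {"exact", "asymptotic"}:
        v.append("diff.p_method: must be 'exact' or 'asymptotic'")
    if config.nmds.restarts < 1:
        v.append("nmds.restarts: must be >= 1")
    e = config.ensemble
    if e.panel_min > e.panel_max:
        v.append("ensemble.panel_min: must not exceed ensemble.panel_max")
    if e.panel_min < 1:
        v.append("ensemble.panel_min: must be >= 1")
    if e.panel_max > config.diff.top_k:
        v.append("ensemble.panel_max: must not exceed diff.top_k")
    if not 0.0 <= e.sensitivity_gate <= 1.0:
        v.append("ensemble.sensitivity_gate: must be in [0, 1]")
    if not 0.0 <= e.specificity_gate <= 1.0:
        v.append("ensemble.specificity_gate: must be in [0, 1]")
    if e.budget < 1:
        v.append("ensemble.budget: must be >= 1")
    if e.replicates < 1:
        v.append("ensemble.replicates: must be >= 1")
    if not 0.0 <= e.ridge_lambda <= 1.0:
        v.append("ensemble.ridge_lambda: must be in [0, 1]")
    sim = config.simulate
    try:
        sim.validate()
    except Exception as exc:
        v.append(f"simulate: {exc}")
    if sim.n_cp < e.train_per_group + 1 or sim.n_control < e.train_per_group + 1:
        v.append(
            "ensemble.train_per_group: each simulated group must exceed it by >= 1"
        )
    return v


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute every stage; returns the manifest (also written to
    ``manifest.json``).  Reruns with the same config are bit-identical.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "artifacts": []}

    def record(path: Path, stage: str, **params) -> None:
        manifest["artifacts"].append(
            {"path": path.name, "stage": stage, "params": params}
        )

    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.stage_seed("simulate"))
        cohort = generate_cohort(sim_cfg)
        tables_dir = out / "subject_tables"
        tables_dir.mkdir(exist_ok=True)
        per_subject = []
        for j, subj in enumerate(cohort.matrix.subjects):
            p = tables_dir / f"{subj.subject_id}.tsv"
            io.write_methylation_table(
                cohort.matrix.select_subjects([subj.subject_id]), p
            )
            per_subject.append(p)
        io.write_subject_metadata(cohort.matrix.subjects, out / "subjects.tsv")
        io.write_annotation(cohort.annotation, out / "annotation.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("site_id\teffect\n")
            for sid, eff in sorted(cohort.truth.items()):
                fh.write(f"{sid}\t{eff}\n")
        record(out / "subjects.tsv", stage, seed=sim_cfg.seed)
        record(out / "annotation.tsv", stage, seed=sim_cfg.seed)
        record(out / "truth.tsv", stage, seed=sim_cfg.seed)

        stage = "intersect"
        singles = []
        meta = {s.subject_id: s for s in io.read_subject_metadata(out / "subjects.tsv")}
        for p in per_subject:
            m = io.read_methylation_table(p)
            m.subjects[0] = meta[m.subjects[0].subject_id]
            singles.append(m)
        matrix = intersect_common_sites(singles)

        stage = "filter"
        informative = diffmeth.filter_informative_sites(
            matrix, threshold=config.filter.threshold
        )
        pd_path = out / "informative_sites.tsv"
        with open(pd_path, "w") as fh:
            fh.write("site_id\n")
            fh.writelines(f"{sid}\n" for sid in informative)
        record(pd_path, stage, threshold=config.filter.threshold,
               n_informative=len(informative))

        stage = "diff-test"
        results = diffmeth.run_differential(matrix, p_method=config.diff.p_method)
        results.to_csv(out / "differential.tsv", sep="\t", index=False)
        top = diffmeth.rank_top_sites(results, k=config.diff.top_k)
        with open(out / "top_sites.tsv", "w") as fh:
            fh.write("rank\tsite_id\n")
            fh.writelines(f"{i + 1}\t{sid}\n" for i, sid in enumerate(top))
        volcano = diffmeth.volcano_table(results, alpha=config.diff.fdr)
        volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
        record(out / "differential.tsv", stage, p_method=config.diff.p_method)
        record(out / "top_sites.tsv", stage, top_k=config.diff.top_k)
        record(out / "volcano.tsv", stage, fdr=config.diff.fdr)

        stage = "delta-ml"
        deltas = load.site_delta(matrix)
        track = load.delta_ml_track(
            deltas, matrix.sites, cohort.annotation.chromosomes
        )
        io.write_bed_track(track, out / "delta_ml.bed")
        gene_mls = load.delta_ml_genes(deltas, matrix.sites, cohort.annotation)
        load.aggregate_by_category(gene_mls, cohort.annotation.category_map).to_csv(
            out / "category_delta_ml.tsv", sep="\t", index=False
        )
        domain_df = load.gene_domain_table(deltas, matrix.sites, cohort.annotation)
        load.aggregate_by_category(domain_df, cohort.annotation.category_map).to_csv(
            out / "category_domain_delta_ml.tsv", sep="\t", index=False
        )
        record(out / "delta_ml.bed", stage, bin_size=track.bin_size)
        record(out / "category_delta_ml.tsv", stage)
        record(out / "category_domain_delta_ml.tsv", stage)

        stage = "nmds"
        sub = matrix.select_sites(informative) if informative else matrix
        dist = nmds.subject_distance(sub, metric=config.nmds.metric)
        embedding = nmds.nmds_embed(
            dist,
            n_restarts=config.nmds.restarts,
            max_iter=config.nmds.max_iter,
            tol=config.nmds.tol,
            seed=config.stage_seed("nmds"),
        )
        with open(out / "nmds_coords.tsv", "w") as fh:
            fh.write("subject_id\tgroup\tx\ty\n")
            for subj, (x, y) in zip(matrix.subjects, embedding.coords):
                fh.write(f"{subj.subject_id}\t{subj.group.value}\t{x:.6f}\t{y:.6f}\n")
        record(out / "nmds_coords.tsv", stage, stress=embedding.stress,
               metric=config.nmds.metric, seed=config.stage_seed("nmds"))

        stage = "search"
        e = config.ensemble
        good, state = ensemble.search_models(
            top,
            matrix,
            budget=e.budget,
            seed=config.stage_seed("search"),
            panel_range=(e.panel_min, e.panel_max),
            reweight_interval=e.reweight_interval,
            boost=e.boost,
            max_good=e.max_good,
            n_replicates=e.replicates,
            train_per_group=e.train_per_group,
            ridge_lambda=e.ridge_lambda,
            sens_gate=e.sensitivity_gate,
            spec_gate=e.specificity_gate,
        )
        ensemble.models_to_json(good, out / "models.json")
        record(out / "models.json", stage, budget=e.budget,
               evaluations=state.evaluations, n_good=len(good),
               seed=config.stage_seed("search"))

        stage = "blinded-vote"
        blinded = generate_blinded_cohort(cohort, seed=config.stage_seed("blinded"))
        metrics_payload: dict = {"n_good_models": len(good)}
        if good:
            votes = ensemble.vote_classify(good, blinded.matrix)
            votes.to_csv(out / "votes.tsv", sep="\t", index=False)
            record(out / "votes.tsv", stage, n_models=len(good),
                   seed=config.stage_seed("blinded"))

            stage = "metrics"
            truth = np.array(
                [blinded.true_groups[s].value for s in blinded.matrix.subject_ids]
            )
            cm = ensemble.compute_metrics(votes["predicted"].to_numpy(), truth)
            roc = ensemble.roc_from_votes(votes["vote_fraction"].to_numpy(), truth)
            theo = ensemble.theoretical_roc(
                good, matrix, n_bootstrap=e.theoretical_bootstrap,
                seed=config.stage_seed("theoretical_roc"),
            )
            metrics_payload.update(
                {
                    "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
                    "percent": cm.as_percent(),
                    "auc": roc.auc,
                    "theoretical_auc": theo.auc,
                    "votes_total_per_subject": int(votes["votes_total"].iloc[0]),
                }
            )
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics_payload, fh, indent=1, sort_keys=True)
        record(out / "metrics.json", "metrics")
    except Exception as exc:  # halt with stage name; keep partial outputs
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
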