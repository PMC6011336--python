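"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
toy genome carrying CpG (CCGG) sites whose baseline methylation follows
a bimodal Beta(0.5, 0.5) landscape (most sites mostly-on or mostly-off),
a minority of planted differential sites whose CP-group mean is shifted
by a configurable effect (default 20 percentage points, signed per site),
Gaussian per-subject noise, and an optional binomial read-depth mode.

The default cohort shape mirrors the study design the pipeline targets:
a 32-subject main cohort (16 CP / 16 control, adolescents) and an
11-subject blinded cohort (6 CP / 5 control, ~4-year-olds) in which the
planted effects may be attenuated to model age-related signal decay.
The hyper/hypo split of planted signs defaults to the 3779:2809
hyper:hypo imbalance observed in the real-data analysis this emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datamodel import (
    CpGSite,
    Gene,
    GenomeAnnotation,
    Group,
    MethylationMatrix,
    Sex,
    Subject,
    ValidationError,
)

__all__ = [
    "BlindedConfig",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_blinded_cohort",
    "add_spikein_standards",
    "toy_annotation",
    "HYPER_FRACTION_DEFAULT",
    "KEGG_TOP_CATEGORIES",
]

#: Default probability that a planted site is hyper-methylated in CP,
#: matching the observed 3779 hyper : 2809 hypo imbalance.
HYPER_FRACTION_DEFAULT = 3779 / (3779 + 2809)

#: Six top-level KEGG pathway map classifications used to label toy genes.
KEGG_TOP_CATEGORIES = (
    "Cellular Processes",
    "Human Diseases",
    "Environmental Information Processing",
    "Genetic Information Processing",
    "Metabolism",
    "Organismal Systems",
)


@dataclass
class BlindedConfig:
    n_cp: int = 6
    n_control: int = 5
    #: Multiplier on the planted effects in the blinded cohort; 1 keeps
    #: the main-cohort signal, 0 makes the cohort indistinguishable from
    #: null data.
    effect_attenuation: float = 1.0


@dataclass
class SimulationConfig:
    n_cp: int = 16
    n_control: int = 16
    n_sites: int = 20_000
    n_differential: int = 200
    #: Group mean difference at planted sites, percentage points.  A
    #: scalar or a per-site sequence of length ``n_differential``.
    effect_size: float | Sequence[float] = 20.0
    baseline_alpha: float = 0.5
    baseline_beta: float = 0.5
    subject_noise_sd: float = 3.0
    read_depth: int | None = None
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    hyper_fraction: float = HYPER_FRACTION_DEFAULT
    genes_per_chromosome: int = 40
    seed: int | None = None
    blinded: BlindedConfig = field(default_factory=BlindedConfig)

    def validate(self) -> None:
        if self.n_differential > self.n_sites:
            raise ValidationError("n_differential exceeds n_sites")
        effects = np.atleast_1d(np.asarray(self.effect_size, dtype=float))
        if (effects < 0).any():
            raise ValidationError("effect_size must be >= 0")
        if effects.size not in (1, self.n_differential):
            raise ValidationError(
                "effect_size must be scalar or length n_differential"
            )
        if not 0.0 <= self.blinded.effect_attenuation <= 1.0:
            raise ValidationError("effect_attenuation must be in [0, 1]")
        if self.n_cp < 1 or self.n_control < 1:
            raise ValidationError("both groups need at least one subject")
        if not 0.0 <= self.hyper_fraction <= 1.0:
            raise ValidationError("hyper_fraction must be in [0, 1]")
        if self.n_sites > self.n_chromosomes * self.chrom_length:
            raise ValidationError("toy genome too small for n_sites")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth needed to audit it.

    ``truth`` maps planted site_id -> signed effect in percentage points,
    positive meaning hyper-methylated in CP.  For blinded cohorts the
    matrix carries ``Group.UNKNOWN`` labels and ``true_groups`` holds the
    hidden assignment.
    """

    matrix: MethylationMatrix
    truth: dict[str, float]
    annotation: GenomeAnnotation
    config: SimulationConfig
    true_groups: dict[str, Group] = field(default_factory=dict)
    warnings: list[dict] = field(default_factory=list)
    # per-site control-group means; retained so a blinded cohort can be
    # generated on the same genome
    baseline: np.ndarray | None = None


def _site_positions(rng: np.random.Generator, cfg: SimulationConfig) -> list[CpGSite]:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_sites // cfg.n_chromosomes)
    per_chrom[: cfg.n_sites % cfg.n_chromosomes] += 1
    sites: list[CpGSite] = []
    for c in range(cfg.n_chromosomes):
        n = int(per_chrom[c])
        positions: set[int] = set()
        while len(positions) < n:
            draw = rng.integers(1, cfg.chrom_length + 1, size=n - len(positions))
            positions.update(int(p) for p in draw)
        for pos in sorted(positions):
            sites.append(CpGSite(f"chr{c + 1}", pos))
    return sites


def toy_annotation(
    rng: np.random.Generator, cfg: SimulationConfig
) -> GenomeAnnotation:
    """Toy gene models on the simulated genome.

    Genes are laid out without overlap on each chromosome, given a random
    strand, a 5'UTR at the strand-aware start, alternating exons/introns,
    and a 1 kb CpG island at the transcription start; each gene is
    assigned one of six KEGG-like top-level categories.
    """
    chromosomes = {
        f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chromosomes)
    }
    genes: list[Gene] = []
    category_map: dict[str, str] = {}
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        slot = cfg.chrom_length // max(cfg.genes_per_chromosome, 1)
        for g in range(cfg.genes_per_chromosome):
            length = int(rng.integers(5_000, 50_001))
            lo = g * slot + 3000
            hi = min((g + 1) * slot - length - 1, cfg.chrom_length - length)
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            utr_len = max(200, length // 10)
            if strand == "+":
                utr = (start, start + utr_len - 1)
            else:
                utr = (end - utr_len + 1, end)
            third = length // 3
            features = {
                "5utr": [utr],
                "exon": [(start, start + third - 1),
                         (end - third + 1, end)],
                "intron": [(start + third, end - third)],
                "cpg_island": [(max(1, tss - 500),
                                min(cfg.chrom_length, tss + 500))],
            }
            gene_id = f"G{c + 1}_{g + 1:03d}"
            genes.append(Gene(gene_id, chrom, start, end, strand, features))
            category_map[gene_id] = KEGG_TOP_CATEGORIES[
                int(rng.integers(len(KEGG_TOP_CATEGORIES)))
            ]
    return GenomeAnnotation(chromosomes, genes, category_map)


def _planted_effects(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(planted site indices, signed effects on the percent scale)."""
    idx = rng.choice(cfg.n_sites, size=cfg.n_differential, replace=False)
    idx.sort()
    effects = np.atleast_1d(np.asarray(cfg.effect_size, dtype=float))
    if effects.size == 1:
        effects = np.full(cfg.n_differential, float(effects[0]))
    signs = np.where(rng.random(cfg.n_differential) < cfg.hyper_fraction, 1.0, -1.0)
    return idx, signs * effects


def _feasible_baselines(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    baseline: np.ndarray,
    planted_idx: np.ndarray,
    signed_effects: np.ndarray,
    warnings: list[dict],
) -> None:
    """Resample planted-site baselines so the full +/-effect shift fits in
    [0, 100]; sites where no draw can fit are left to clip, with a warning
    record.  Mutates ``baseline`` in place."""
    for _ in range(200):
        means = baseline[planted_idx]
        bad = (means + signed_effects > 100.0) | (means + signed_effects < 0.0)
        feasible = np.abs(signed_effects) <= 100.0
        bad &= feasible
        if not bad.any():
            break
        baseline[planted_idx[bad]] = (
            rng.beta(cfg.baseline_alpha, cfg.baseline_beta, int(bad.sum())) * 100.0
        )
    means = baseline[planted_idx]
    clipped = (means + signed_effects > 100.0) | (means + signed_effects < 0.0)
    for j in np.nonzero(clipped)[0]:
        warnings.append(
            {
                "site_index": int(planted_idx[j]),
                "reason": "planted shift clipped to [0, 100]",
                "baseline": float(means[j]),
                "effect": float(signed_effects[j]),
            }
        )


def _subject_roster(
    rng: np.random.Generator,
    n_cp: int,
    n_control: int,
    *,
    prefix_cp: str = "CP",
    prefix_ctrl: str = "CTRL",
    age_cp: tuple[float, float] = (14.7, 3.3),
    age_ctrl: tuple[float, float] = (15.0, 2.2),
    male_fraction: float = 13 / 16,
    blinded: bool = False,
) -> tuple[list[Subject], dict[str, Group]]:
    subjects: list[Subject] = []
    true_groups: dict[str, Group] = {}
    specs = [(prefix_cp, Group.CP, n_cp, age_cp), (prefix_ctrl, Group.CONTROL, n_control, age_ctrl)]
    for prefix, group, n, (mu, sd) in specs:
        for i in range(n):
            sid = f"{prefix}{i + 1:02d}"
            age = float(np.clip(rng.normal(mu, sd), 0.5, 21.0))
            sex = Sex.MALE if rng.random() < male_fraction else Sex.FEMALE
            label = Group.UNKNOWN if blinded else group
            subjects.append(Subject(sid, label, age=round(age, 1), sex=sex))
            true_groups[sid] = group
    return subjects, true_groups


def _scores(
    rng: np.random.Generator,
    means: np.ndarray,
    noise_sd: float,
    read_depth: int | None,
) -> np.ndarray:
    if noise_sd > 0:
        vals = means + rng.normal(0.0, noise_sd, size=means.shape)
    else:
        vals = means.copy()
    np.clip(vals, 0.0, 100.0, out=vals)
    if read_depth is not None:
        counts = rng.binomial(read_depth, vals / 100.0)
        vals = 100.0 * counts / read_depth
    return vals


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the main (labelled) cohort; deterministic given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    warnings: list[dict] = []

    sites = _site_positions(rng, config)
    annotation = toy_annotation(rng, config)
    baseline = rng.beta(config.baseline_alpha, config.baseline_beta, config.n_sites) * 100.0
    planted_idx, signed_effects = _planted_effects(rng, config)
    _feasible_baselines(rng, config, baseline, planted_idx, signed_effects, warnings)

    cp_mean = baseline.copy()
    cp_mean[planted_idx] = np.clip(cp_mean[planted_idx] + signed_effects, 0.0, 100.0)

    subjects, true_groups = _subject_roster(rng, config.n_cp, config.n_control)
    means = np.empty((config.n_sites, len(subjects)))
    for j, s in enumerate(subjects):
        means[:, j] = cp_mean if s.group is Group.CP else baseline
    scores = _scores(rng, means, config.subject_noise_sd, config.read_depth)

    matrix = MethylationMatrix(sites, subjects, scores)
    truth = {
        sites[i].site_id: float(e) for i, e in zip(planted_idx, signed_effects)
    }
    return SyntheticCohort(
        matrix=matrix,
        truth=truth,
        annotation=annotation,
        config=config,
        true_groups=true_groups,
        warnings=warnings,
        baseline=baseline,
    )


def generate_blinded_cohort(
    parent: SyntheticCohort,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Blinded validation cohort on the parent's genome and planted sites.

    Planted effects are multiplied by ``blinded.effect_attenuation``
    (age-related signal decay); subjects carry ``Group.UNKNOWN`` labels
    while ``true_groups`` records the hidden assignment.
    """
    cfg = config or parent.config
    cfg.validate()
    if parent.baseline is None:
        raise ValueError("parent cohort lacks baseline means; regenerate it")
    rng = np.random.default_rng(parent.config.seed + 1 if seed is None and parent.config.seed is not None else seed)

    sites = parent.matrix.sites
    index = parent.matrix.site_index()
    atten = cfg.blinded.effect_attenuation
    cp_mean = parent.baseline.copy()
    for sid, eff in parent.truth.items():
        i = index[sid]
        cp_mean[i] = np.clip(parent.baseline[i] + atten * eff, 0.0, 100.0)

    subjects, true_groups = _subject_roster(
        rng,
        cfg.blinded.n_cp,
        cfg.blinded.n_control,
        prefix_cp="B-CP",
        prefix_ctrl="B-CTRL",
        age_cp=(3.7, 1.5),
        age_ctrl=(4.2, 1.4),
        blinded=True,
    )
    means = np.empty((len(sites), len(subjects)))
    for j, s in enumerate(subjects):
        means[:, j] = cp_mean if true_groups[s.subject_id] is Group.CP else parent.baseline
    scores = _scores(rng, means, cfg.subject_noise_sd, cfg.read_depth)

    matrix = MethylationMatrix(sites, subjects, scores)
    truth = {sid: atten * eff for sid, eff in parent.truth.items()}
    return SyntheticCohort(
        matrix=matrix,
        truth=truth,
        annotation=parent.annotation,
        config=cfg,
        true_groups=true_groups,
        baseline=parent.baseline,
    )


def add_spikein_standards(
    matrix: MethylationMatrix,
    levels: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MethylationMatrix:
    """Append known-composition spike-in control sites, one per level.

    The analog of laboratory standards synthesized with a known
    methyl-CpG fraction: each appended site scores at its nominal level
    (plus optional Gaussian noise) for every subject, on a dedicated
    ``spikein`` pseudo-chromosome, and is flagged in
    ``matrix.metadata["spikein_levels"]``.
    """
    levels = [float(v) for v in levels]
    for v in levels:
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"spike-in level {v} outside [0, 100]")
    if not levels:
        return matrix
    rng = np.random.default_rng(seed)
    n_subj = matrix.n_subjects
    rows = np.empty((len(levels), n_subj))
    spike_sites: list[CpGSite] = []
    flags: dict[str, float] = dict(matrix.metadata.get("spikein_levels", {}))
    existing = sum(1 for s in matrix.sites if s.chrom == "spikein")
    for i, v in enumerate(levels):
        vals = np.full(n_subj, v)
        if noise_sd > 0:
            vals = np.clip(vals + rng.normal(0.0, noise_sd, n_subj), 0.0, 100.0)
        rows[i] = vals
        site = CpGSite("spikein", existing + i + 1)
        spike_sites.append(site)
        flags[site.site_id] = v
    meta = dict(matrix.metadata)
    meta["spikein_levels"] = flags
    return MethylationMatrix(
        matrix.sites + spike_sites,
        matrix.subjects,
        np.vstack([matrix.scores, rows]),
        metadata=meta,
    )
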