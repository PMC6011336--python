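"""Core data structures for CpG methylation analysis.

The universal currency of the pipeline is the :class:`MethylationMatrix`:
a sites x subjects matrix of per-CpG methylation scores on the percent
scale [0, 100], where each score is proportional to the probability that
the site is methylated in the sampled cell population.  "CpG site" here
means the CCGG recognition motif of the methyl-sensitive restriction
enzyme HpaII; because CCGG is its own reverse complement, a site is
identified by (chromosome, position) alone, with no strand.

Coordinates are 1-based inclusive throughout; BED output (see
:mod:`epimethyl.io`) converts to 0-based half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "CpGSite",
    "Subject",
    "MethylationMatrix",
    "Gene",
    "GenomeAnnotation",
    "ValidationError",
    "EmptyIntersectionError",
    "intersect_common_sites",
    "PROMOTER_BP",
]

#: Promoter extent prepended to the strand-aware gene start, in bp.
PROMOTER_BP = 2000


class ValidationError(ValueError):
    """Raised when a data structure violates its invariants."""


class EmptyIntersectionError(ValueError):
    """Raised when no CpG site is shared by all subjects; the pipeline
    cannot proceed without a common site set."""


class Group(str, enum.Enum):
    CP = "CP"
    CONTROL = "control"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Group":
        t = str(text).strip().lower()
        if t in {"cp", "case"}:
            return cls.CP
        if t in {"control", "ctrl", "non-cp", "noncp"}:
            return cls.CONTROL
        if t in {"unknown", "blinded", "na", ""}:
            return cls.UNKNOWN
        raise ValidationError(f"unrecognized group label: {text!r}")


class Sex(str, enum.Enum):
    MALE = "M"
    FEMALE = "F"


@dataclass(frozen=True, order=True)
class CpGSite:
    """A single HpaII CCGG site, 1-based position of the first C."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"site position must be >= 1, got {self.pos}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @classmethod
    def from_id(cls, site_id: str) -> "CpGSite":
        chrom, _, pos = site_id.rpartition(":")
        return cls(chrom=chrom, pos=int(pos))


@dataclass
class Subject:
    subject_id: str
    group: Group
    age: float | None = None
    sex: Sex | None = None


class MethylationMatrix:
    """Sites x subjects methylation score matrix on the percent scale.

    Parameters
    ----------
    sites:
        Ordered CpG sites (rows).
    subjects:
        Ordered subjects (columns).
    scores:
        Array of shape ``(len(sites), len(subjects))`` with values in
        [0, 100]; no missing values are permitted (missingness is handled
        upstream by site intersection, never by imputation).
    """

    def __init__(
        self,
        sites: Sequence[CpGSite],
        subjects: Sequence[Subject],
        scores: np.ndarray,
        *,
        metadata: dict | None = None,
        validate: bool = True,
    ) -> None:
        self.sites = list(sites)
        self.subjects = list(subjects)
        self.scores = np.asarray(scores, dtype=float)
        self.metadata: dict = metadata or {}
        if validate:
            self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_sites, n_subj = len(self.sites), len(self.subjects)
        if self.scores.shape != (n_sites, n_subj):
            raise ValidationError(
                f"scores shape {self.scores.shape} != ({n_sites}, {n_subj})"
            )
        if n_sites and n_subj:
            if not np.isfinite(self.scores).all():
                raise ValidationError("scores contain NaN or infinite values")
            lo, hi = self.scores.min(), self.scores.max()
            if lo < 0.0 or hi > 100.0:
                raise ValidationError(
                    f"scores outside [0, 100]: range [{lo}, {hi}]"
                )
        keys = {(s.chrom, s.pos) for s in self.sites}
        if len(keys) != n_sites:
            raise ValidationError("duplicate (chrom, pos) in site list")
        ids = {s.subject_id for s in self.subjects}
        if len(ids) != n_subj:
            raise ValidationError("duplicate subject ids")

    # -- basic accessors -----------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects], dtype=object)

    def group_mask(self, group: Group) -> np.ndarray:
        return np.array([s.group is group for s in self.subjects], dtype=bool)

    def site_index(self) -> dict[str, int]:
        return {s.site_id: i for i, s in enumerate(self.sites)}

    # -- transforms ----------------------------------------------------
    def select_sites(self, site_ids: Iterable[str]) -> "MethylationMatrix":
        """Row subset in the order given; unknown ids raise KeyError."""
        index = self.site_index()
        rows = [index[sid] for sid in site_ids]
        return MethylationMatrix(
            [self.sites[i] for i in rows],
            self.subjects,
            self.scores[rows, :],
            metadata=dict(self.metadata),
            validate=False,
        )

    def select_subjects(self, subject_ids: Iterable[str]) -> "MethylationMatrix":
        index = {s.subject_id: j for j, s in enumerate(self.subjects)}
        cols = [index[sid] for sid in subject_ids]
        return MethylationMatrix(
            self.sites,
            [self.subjects[j] for j in cols],
            self.scores[:, cols],
            metadata=dict(self.metadata),
            validate=False,
        )

    def to_fractions(self) -> np.ndarray:
        """Scores rescaled to the [0, 1] fraction scale (copy)."""
        return self.scores / 100.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.site_ids, columns=self.subject_ids
        )


def intersect_common_sites(
    matrices: Sequence[MethylationMatrix],
) -> MethylationMatrix:
    """Merge per-subject matrices on the sites present in *every* input.

    The output sites are sorted by (chrom, pos); columns follow the input
    order.  Intersection is the pipeline's only treatment of missing
    sites.  Raises :class:`EmptyIntersectionError` when nothing is shared.
    """
    if len(matrices) < 2:
        raise ValueError("intersection needs at least two input matrices")
    common: set[tuple[str, int]] | None = None
    for m in matrices:
        keys = {(s.chrom, s.pos) for s in m.sites}
        common = keys if common is None else (common & keys)
    assert common is not None
    if not common:
        raise EmptyIntersectionError(
            "no CpG site is present in all subjects"
        )
    ordered = sorted(common)
    sites = [CpGSite(chrom, pos) for chrom, pos in ordered]

    subjects: list[Subject] = []
    columns: list[np.ndarray] = []
    for m in matrices:
        index = {(s.chrom, s.pos): i for i, s in enumerate(m.sites)}
        rows = np.fromiter((index[k] for k in ordered), dtype=int, count=len(ordered))
        subjects.extend(m.subjects)
        columns.append(m.scores[rows, :])
    scores = np.hstack(columns)
    return MethylationMatrix(sites, subjects, scores)


# ---------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------

#: Gene-structure feature classes used for methylation-load breakdowns.
FEATURE_CLASSES = ("promoter", "5utr", "exon", "intron", "cpg_island")


@dataclass
class Gene:
    """An annotated gene: 1-based inclusive body span plus optional
    sub-feature spans (5'UTR, exons, introns, CpG islands)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    features: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be +/-, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid gene span [{self.start}, {self.end}]"
            )


@dataclass
class GenomeAnnotation:
    """Chromosome sizes, gene models and an optional user-supplied
    gene -> functional-category map (no live database lookups)."""

    chromosomes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            length = self.chromosomes.get(g.chrom)
            if length is not None and g.end > length:
                raise ValidationError(
                    f"gene {g.gene_id} extends past {g.chrom} length {length}"
                )

    def gene_span_with_promoter(self, gene: Gene) -> tuple[int, int]:
        """Gene body extended by the 2 kb promoter on the strand-aware
        upstream side, clipped to the chromosome."""
        length = self.chromosomes.get(gene.chrom)
        if gene.strand == "+":
            start, end = gene.start - PROMOTER_BP, gene.end
        else:
            start, end = gene.start, gene.end + PROMOTER_BP
        start = max(1, start)
        if length is not None:
            end = min(end, length)
        return start, end
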