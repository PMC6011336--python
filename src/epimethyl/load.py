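"""Differential methylation load (DML) over genomic spans.

DML over a span is the sum of per-site group differences (control mean
minus CP mean, percentage points) divided by the number of CpG sites in
the span; positive values mean more methylation in controls.  Spans are
1-Mbp tiling intervals (genome track), gene bodies extended by their
2 kb upstream promoters, or gene-structure domains crossed with
user-supplied functional categories.

Track intervals carry a three-way hotspot class: an interval is
EQUIVALENT when |DML| is less than twice the genome-wide average |DML|
(over non-empty intervals); otherwise the sign picks CONTROL_HIGHER or
CP_HIGHER.
"""

from __future__ import annotations

import enum
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    CpGSite,
    GenomeAnnotation,
    MethylationMatrix,
    ValidationError,
)
from .diffmeth import group_means

__all__ = [
    "HotspotClass",
    "Interval",
    "MLTrack",
    "GeneML",
    "site_delta",
    "delta_ml_track",
    "delta_ml_genes",
    "gene_domain_table",
    "aggregate_by_category",
    "BIN_SIZE_DEFAULT",
]

#: Default tiling interval for the genome-wide DML track, bp.
BIN_SIZE_DEFAULT = 1_000_000


class HotspotClass(str, enum.Enum):
    CONTROL_HIGHER = "control_higher"
    CP_HIGHER = "cp_higher"
    EQUIVALENT = "equivalent"


@dataclass
class Interval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    n_sites: int
    delta_ml: float
    hotspot_class: HotspotClass
    empty: bool = False


@dataclass
class MLTrack:
    intervals: list[Interval]
    bin_size: int = BIN_SIZE_DEFAULT

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "n_sites": [iv.n_sites for iv in self.intervals],
                "delta_ml": [iv.delta_ml for iv in self.intervals],
                "hotspot_class": [iv.hotspot_class.value for iv in self.intervals],
            }
        )


@dataclass
class GeneML:
    gene_id: str
    chrom: str
    span_start: int
    span_end: int
    n_sites: int
    delta_ml: float
    category: str | None = None
    site_ids: list[str] = field(default_factory=list)


def site_delta(matrix: MethylationMatrix) -> np.ndarray:
    """Per-site group difference, control mean - CP mean (points).

    Positive values mean the control group is more methylated."""
    mean_ctrl, mean_cp = group_means(matrix)
    return mean_ctrl - mean_cp


def _classify(
    delta_mls: np.ndarray, empty: np.ndarray
) -> tuple[list[HotspotClass], float]:
    """Hotspot classes for all intervals plus the threshold used.

    Threshold = 2 x mean |DML| over non-empty intervals; a mean of the
    signed values would sit near zero and classify almost nothing as
    equivalent.  A DML of exactly 0 is always EQUIVALENT (degenerate
    genome with no signal)."""
    occupied = ~empty
    thr = 2.0 * float(np.mean(np.abs(delta_mls[occupied]))) if occupied.any() else 0.0
    classes: list[HotspotClass] = []
    for dml in delta_mls:
        if dml == 0.0 or abs(dml) < thr:
            classes.append(HotspotClass.EQUIVALENT)
        elif dml > 0:
            classes.append(HotspotClass.CONTROL_HIGHER)
        else:
            classes.append(HotspotClass.CP_HIGHER)
    return classes, thr


def delta_ml_track(
    site_deltas: np.ndarray,
    sites: list[CpGSite],
    chrom_lengths: dict[str, int],
    bin_size: int = BIN_SIZE_DEFAULT,
) -> MLTrack:
    """DML over tiling intervals of ``bin_size`` bp per chromosome.

    Each interval's DML is the sum of its sites' deltas divided by the
    site count; empty intervals get DML 0 and an ``empty`` flag.  The
    final interval of a chromosome is truncated at the chromosome end.
    """
    deltas = np.asarray(site_deltas, dtype=float)
    if deltas.size != len(sites):
        raise ValidationError("site_deltas and sites disagree in length")
    by_chrom: dict[str, list[tuple[int, float]]] = {c: [] for c in chrom_lengths}
    for site, d in zip(sites, deltas):
        if site.chrom in by_chrom:
            by_chrom[site.chrom].append((site.pos, d))

    records: list[tuple[str, int, int, int, float, bool]] = []
    for chrom, length in chrom_lengths.items():
        entries = by_chrom[chrom]
        pos = np.array([p for p, _ in entries], dtype=int)
        val = np.array([v for _, v in entries], dtype=float)
        n_bins = max(1, -(-length // bin_size))
        which = np.minimum((pos - 1) // bin_size, n_bins - 1) if pos.size else pos
        sums = np.bincount(which, weights=val, minlength=n_bins) if pos.size else np.zeros(n_bins)
        counts = np.bincount(which, minlength=n_bins) if pos.size else np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            start = b * bin_size + 1
            end = min((b + 1) * bin_size, length)
            n = int(counts[b])
            dml = float(sums[b] / n) if n else 0.0
            records.append((chrom, start, end, n, dml, n == 0))

    dmls = np.array([r[4] for r in records])
    empty = np.array([r[5] for r in records])
    classes, _ = _classify(dmls, empty)
    intervals = [
        Interval(chrom, start, end, n, dml, cls, empty=e)
        for (chrom, start, end, n, dml, e), cls in zip(records, classes)
    ]
    return MLTrack(intervals, bin_size=bin_size)


def delta_ml_genes(
    site_deltas: np.ndarray,
    sites: list[CpGSite],
    annotation: GenomeAnnotation,
) -> list[GeneML]:
    """DML per gene over the gene body plus its 2 kb upstream promoter
    (strand-aware, clipped to the chromosome; span ends inclusive).
    Sites falling in overlapping genes count toward each.  Genes on
    chromosomes absent from the annotation's size table are skipped with
    a warning."""
    deltas = np.asarray(site_deltas, dtype=float)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {s.chrom for s in sites}:
        idx = [i for i, s in enumerate(sites) if s.chrom == chrom]
        pos = np.array([sites[i].pos for i in idx], dtype=int)
        order = np.argsort(pos)
        by_chrom[chrom] = (
            pos[order],
            deltas[np.array(idx)[order]],
            [sites[i].site_id for i in np.array(idx)[order]],
        )

    out: list[GeneML] = []
    for gene in annotation.genes:
        if gene.chrom not in annotation.chromosomes:
            _warnings.warn(
                f"gene {gene.gene_id} on unknown chromosome {gene.chrom}; skipped"
            )
            continue
        start, end = annotation.gene_span_with_promoter(gene)
        pos, val, ids = by_chrom.get(gene.chrom, (np.array([], dtype=int), np.array([]), []))
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        n = int(hi - lo)
        dml = float(val[lo:hi].sum() / n) if n else 0.0
        out.append(
            GeneML(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                span_start=start,
                span_end=end,
                n_sites=n,
                delta_ml=dml,
                category=annotation.category_map.get(gene.gene_id),
                site_ids=list(ids[lo:hi]),
            )
        )
    return out


def gene_domain_table(
    site_deltas: np.ndarray,
    sites: list[CpGSite],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Per (gene, structural domain) DML table.

    Domains are the annotated feature classes (promoter, 5'UTR, exon,
    intron, CpG island); the promoter is derived from the strand-aware
    2 kb upstream span.  Rows with zero sites are omitted.
    """
    deltas = np.asarray(site_deltas, dtype=float)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in sites}:
        idx = np.array([i for i, s in enumerate(sites) if s.chrom == chrom])
        pos = np.array([sites[i].pos for i in idx], dtype=int)
        order = np.argsort(pos)
        by_chrom[chrom] = (pos[order], deltas[idx[order]])

    rows = []
    for gene in annotation.genes:
        pos, val = by_chrom.get(gene.chrom, (np.array([], dtype=int), np.array([])))
        if gene.strand == "+":
            promoter = (max(1, gene.start - 2000), gene.start - 1)
        else:
            promoter = (gene.end + 1, gene.end + 2000)
        spans = {"promoter": [promoter]}
        spans.update(gene.features)
        for domain, span_list in spans.items():
            total, count = 0.0, 0
            for lo_bp, hi_bp in span_list:
                lo = np.searchsorted(pos, lo_bp, side="left")
                hi = np.searchsorted(pos, hi_bp, side="right")
                total += float(val[lo:hi].sum())
                count += int(hi - lo)
            if count:
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "domain": domain,
                        "n_sites": count,
                        "delta_ml": total / count,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "domain", "n_sites", "delta_ml"])


def aggregate_by_category(
    gene_mls: "list[GeneML] | pd.DataFrame",
    category_map: dict[str, str],
) -> pd.DataFrame:
    """Mean +/- SEM of gene-level DML per (category, domain).

    Accepts either :func:`delta_ml_genes` output (whole-gene-body rows)
    or a :func:`gene_domain_table` DataFrame.  Genes without sites are
    excluded; unmapped genes land in an ``unclassified`` bucket; a
    single-gene cell reports SEM 0 with ``n_genes`` 1 flagging it.
    """
    if isinstance(gene_mls, pd.DataFrame):
        df = gene_mls.copy()
        if "domain" not in df.columns:
            df["domain"] = "gene_body"
    else:
        df = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in gene_mls],
                "domain": "gene_body",
                "n_sites": [g.n_sites for g in gene_mls],
                "delta_ml": [g.delta_ml for g in gene_mls],
            }
        )
    df = df[df["n_sites"] > 0]
    if df.empty:
        return pd.DataFrame(
            columns=["category", "domain", "mean_delta_ml", "sem", "n_genes"]
        )
    df["category"] = df["gene_id"].map(lambda g: category_map.get(g, "unclassified"))
    grouped = df.groupby(["category", "domain"], sort=True)["delta_ml"]
    out = grouped.agg(
        mean_delta_ml="mean",
        sem=lambda x: float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
        n_genes="count",
    ).reset_index()
    return out
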