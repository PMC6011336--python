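"""Readers and writers for the pipeline's plain-text formats.

Methylation score tables and subject metadata are tab-separated; DML
tracks are BED (0-based half-open, score column carries the DML value at
6-decimal precision); gene annotations are a BED-like TSV with optional
feature rows.  All coordinates are 1-based inclusive in memory and only
converted at the BED boundary.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

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
from .load import HotspotClass, Interval, MLTrack

__all__ = [
    "ParseError",
    "read_methylation_table",
    "write_methylation_table",
    "read_subject_metadata",
    "write_subject_metadata",
    "write_bed_track",
    "read_bed_track",
    "read_annotation",
    "write_annotation",
    "read_category_map",
]

_TABLE_COLUMNS = ("chrom", "pos", "score")
_BED_PRECISION = 6


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_methylation_table(path, subject_id: str | None = None) -> MethylationMatrix:
    """Read one subject's per-CpG score table (TSV: chrom, pos, score).

    The subject id defaults to the file stem; the subject group is
    UNKNOWN until metadata is attached.  Scores are validated into
    [0, 100] and parse failures name the 1-based line number.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    sites: list[CpGSite] = []
    scores: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        if tuple(h.strip().lower() for h in header[:3]) != _TABLE_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header chrom<TAB>pos<TAB>score"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            chrom = row[0].strip()
            try:
                pos = int(row[1])
                score = float(row[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric pos or score"
                ) from None
            if not 0.0 <= score <= 100.0:
                raise ValidationError(
                    f"{path}: line {lineno}: score {score} outside [0, 100]"
                )
            try:
                sites.append(CpGSite(chrom, pos))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            scores.append(score)
    subject = Subject(sid, Group.UNKNOWN)
    return MethylationMatrix(
        sites, [subject], np.asarray(scores, dtype=float).reshape(-1, 1)
    )


def write_methylation_table(matrix: MethylationMatrix, path, column: int = 0) -> None:
    """Write one subject column back to the TSV table format."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for site, score in zip(matrix.sites, matrix.scores[:, column]):
            writer.writerow([site.chrom, site.pos, repr(float(score))])


def read_subject_metadata(path) -> list[Subject]:
    """TSV with columns subject_id, group, age, sex (age/sex optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(required)}")
    subjects = []
    for _, row in df.iterrows():
        age = None
        if "age" in df.columns and pd.notna(row.get("age")) and str(row["age"]).strip():
            age = float(row["age"])
        sex = None
        if "sex" in df.columns and pd.notna(row.get("sex")) and str(row["sex"]).strip():
            sex = Sex(str(row["sex"]).strip().upper()[0])
        subjects.append(Subject(str(row["subject_id"]), Group.parse(row["group"]), age=age, sex=sex))
    return subjects


def write_subject_metadata(subjects: list[Subject], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "group", "age", "sex"])
        for s in subjects:
            writer.writerow(
                [
                    s.subject_id,
                    s.group.value,
                    "" if s.age is None else s.age,
                    "" if s.sex is None else s.sex.value,
                ]
            )


# ---------------------------------------------------------------------
# BED track round trip
# ---------------------------------------------------------------------


def write_bed_track(track: MLTrack, path, name: str = "delta_ML") -> None:
    """Write a DML track as BED: 0-based half-open coordinates, the
    score column carrying DML at 6 decimals.  Intervals must be sorted
    within each chromosome and non-overlapping."""
    last: dict[str, int] = {}
    for iv in track.intervals:
        if iv.chrom in last and iv.start <= last[iv.chrom]:
            raise ValidationError(
                f"intervals unsorted or overlapping at {iv.chrom}:{iv.start}"
            )
        last[iv.chrom] = iv.end
    with open(path, "w", newline="") as fh:
        fh.write(f'track name={name} type=bedGraph bin_size={track.bin_size}\n')
        for iv in track.intervals:
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start - 1),  # 1-based inclusive -> 0-based half-open
                        str(iv.end),
                        f"n={iv.n_sites}",
                        f"{iv.delta_ml:.{_BED_PRECISION}f}",
                        iv.hotspot_class.value,
                    ]
                )
                + "\n"
            )


def read_bed_track(path) -> MLTrack:
    intervals: list[Interval] = []
    bin_size = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("track"):
                for token in line.split():
                    if token.startswith("bin_size="):
                        bin_size = int(token.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 fields")
            n_sites = int(parts[3].removeprefix("n="))
            intervals.append(
                Interval(
                    chrom=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    n_sites=n_sites,
                    delta_ml=float(parts[4]),
                    hotspot_class=HotspotClass(parts[5]),
                    empty=n_sites == 0,
                )
            )
    return MLTrack(intervals, bin_size=bin_size or 1_000_000)


# ---------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    """BED-like TSV: ``chromsize`` rows, ``gene`` rows, and ``feature``
    rows (gene_id, class, start, end); 1-based inclusive coordinates."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for chrom, length in annotation.chromosomes.items():
            writer.writerow(["chromsize", chrom, length])
        for g in annotation.genes:
            writer.writerow(["gene", g.gene_id, g.chrom, g.start, g.end, g.strand])
            for cls, spans in g.features.items():
                for start, end in spans:
                    writer.writerow(["feature", g.gene_id, cls, start, end])


def read_annotation(path, category_map: dict[str, str] | None = None) -> GenomeAnnotation:
    chromosomes: dict[str, int] = {}
    genes: dict[str, Gene] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not row[0].strip():
                continue
            kind = row[0]
            try:
                if kind == "chromsize":
                    chromosomes[row[1]] = int(row[2])
                elif kind == "gene":
                    genes[row[1]] = Gene(row[1], row[2], int(row[3]), int(row[4]), row[5])
                elif kind == "feature":
                    genes[row[1]].features.setdefault(row[2], []).append(
                        (int(row[3]), int(row[4]))
                    )
                else:
                    raise ParseError(f"{path}: line {lineno}: unknown row kind {kind!r}")
            except (IndexError, ValueError, KeyError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return GenomeAnnotation(chromosomes, list(genes.values()), category_map or {})


def read_category_map(path) -> dict[str, str]:
    """Two-column TSV gene_id -> functional category (user-supplied)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"], dtype=str)
    return dict(zip(df["gene_id"], df["category"]))
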