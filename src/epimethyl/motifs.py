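"""HpaII (CCGG) motif census over a genome FASTA.

HpaII cuts CCGG only when the internal CpG is unmethylated, so the set
of CCGG motifs in a reference genome is the universe of sites the assay
can interrogate.  CCGG is its own reverse complement and cannot overlap
itself, so a single-strand non-overlapping count equals the site count.
"""

from __future__ import annotations

from pyfaidx import Fasta

__all__ = ["count_ccgg", "ccgg_census", "MOTIF"]

MOTIF = "CCGG"


def count_ccgg(sequence: str) -> int:
    """Number of CCGG motifs in one sequence (case-insensitive; runs of
    N never match)."""
    return sequence.upper().count(MOTIF)


def ccgg_census(fasta_path) -> dict[str, int]:
    """Per-chromosome CCGG counts from a FASTA file; the ``total`` key
    holds the genome-wide sum."""
    counts: dict[str, int] = {}
    with Fasta(str(fasta_path), rebuild=True, build_index=True) as fa:
        for name in fa.keys():
            counts[name] = count_ccgg(str(fa[name][:]))
    counts["total"] = sum(counts.values())
    return counts
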