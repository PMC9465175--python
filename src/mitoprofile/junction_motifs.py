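"""Fixed windows around gene junctions and conserved-motif reporting.

Windows are anchored on annotation coordinates rather than on a sequence
alignment: the window covers the last ``flank_a`` bases of the upstream gene
through the first ``flank_b`` bases of the downstream gene on the *reading
strand of the upstream gene*.  Overlapping genes are handled by coordinate
arithmetic (the shared bases appear once), so the window length is
``flank_a + flank_b + gap`` where ``gap`` is the signed intergenic gap.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .annotation_io import (
    MINUS,
    PLUS,
    AnnotationTable,
    GenomeRecord,
    extract_span,
    reverse_complement,
)

__all__ = [
    "JunctionWindow",
    "junction_window",
    "motif_scan",
    "consensus",
    "write_windows_fasta",
]


@dataclass(frozen=True)
class JunctionWindow:
    """Junction-spanning sequence window on the reading strand of gene_a."""

    genome_id: str
    gene_a: str
    gene_b: str
    seq: str
    offset_of_junction: int  # bases of gene_a context before the junction


def junction_window(
    genome: GenomeRecord,
    table: AnnotationTable,
    gene_a: str,
    gene_b: str,
    flank_a: int = 15,
    flank_b: int = 15,
    max_separation: int = 50,
) -> JunctionWindow:
    """Extract the window around the gene_a/gene_b junction.

    Both genes must be annotated and within ``max_separation`` bp of each
    other (overlaps allowed).  For a minus-strand gene_a the window is the
    reverse complement of the corresponding plus-strand span.
    """
    a = table.feature(gene_a)
    b = table.feature(gene_b)
    L = table.genome_length

    def wrap(pos: int) -> int:
        return (pos - 1) % L + 1

    if a.strand == PLUS:
        gap = b.start - a.end - 1
        if gap < -L // 2:
            gap += L
        lo, hi = wrap(a.end - flank_a + 1), wrap(b.start + flank_b - 1)
        strand = PLUS
    else:
        # reading direction of a minus-strand gene runs toward lower coordinates
        gap = a.start - b.end - 1
        if gap < -L // 2:
            gap += L
        lo, hi = wrap(b.end - flank_b + 1), wrap(a.start + flank_a - 1)
        strand = MINUS
    if abs(gap) > max_separation:
        raise ValueError(
            f"{gene_a} and {gene_b} are separated by {gap} bp "
            f"(> max_separation {max_separation})"
        )
    seq = extract_span(genome, lo, hi, PLUS)
    if strand == MINUS:
        seq = reverse_complement(seq)
    return JunctionWindow(
        genome_id=genome.id,
        gene_a=gene_a,
        gene_b=gene_b,
        seq=seq,
        offset_of_junction=flank_a,
    )


def motif_scan(
    windows: Iterable[JunctionWindow],
    motif: str,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Occurrences of ``motif`` in each window with at most ``max_mismatch``.

    Returns a table with one row per occurrence: genome_id, gene_a, gene_b,
    position (1-based within the window), mismatches.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper().replace("U", "T")
    rows = []
    for w in windows:
        if len(motif) > len(w.seq):
            warnings.warn(
                f"motif longer than window {w.gene_a}/{w.gene_b} of {w.genome_id}"
            )
            continue
        for i in range(len(w.seq) - len(motif) + 1):
            mm = sum(1 for x, y in zip(w.seq[i : i + len(motif)], motif) if x != y)
            if mm <= max_mismatch:
                rows.append(
                    {
                        "genome_id": w.genome_id,
                        "gene_a": w.gene_a,
                        "gene_b": w.gene_b,
                        "position": i + 1,
                        "mismatches": mm,
                    }
                )
    return pd.DataFrame(
        rows, columns=["genome_id", "gene_a", "gene_b", "position", "mismatches"]
    )


def consensus(windows: Iterable[JunctionWindow]) -> tuple[str, list[float]]:
    """Per-column modal base and conservation fraction across windows.

    Windows of unequal length are trimmed to the shortest with a warning.
    Ties are broken in A < C < G < T order.
    """
    seqs = [w.seq for w in windows]
    if not seqs:
        raise ValueError("no windows given")
    m = min(len(s) for s in seqs)
    if any(len(s) != m for s in seqs):
        warnings.warn("windows of unequal length; trimmed to the shortest")
        seqs = [s[:m] for s in seqs]
    cons = []
    fractions = []
    for col in range(m):
        tally = Counter(s[col] for s in seqs)
        best = max(sorted(tally), key=lambda b: tally[b])  # sorted => A<C<G<T ties
        cons.append(best)
        fractions.append(tally[best] / len(seqs))
    return "".join(cons), fractions


def write_windows_fasta(windows: Iterable[JunctionWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.genome_id}|{w.gene_a}|{w.gene_b}\n{w.seq}\n")
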