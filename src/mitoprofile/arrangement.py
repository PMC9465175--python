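"""Gene-arrangement accounting on the circle.

Derives, from an ordered annotation table, the quantities a mitogenome
organisation table reports: feature sizes, signed intergenic nucleotides
(IGN; negative = overlap), per-class counts and length totals, spacer and
overlap statistics, and a canonical gene-order signature for cross-genome
comparison.

The signed gap is defined strictly as ``next.start - prev.end - 1`` on the
circle.  Published IGN columns do not always match their own coordinates, so
summaries can be computed either from the coordinates (``computed``) or from
a verbatim printed column (``printed``); the same switch exists for feature
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from ._round import round_half_up
from .annotation_io import (
    FEATURE_TABLE_HEADER,
    AnnotationTable,
    FeatureAnnotation,
    GeneClass,
)

__all__ = [
    "ArrangementRow",
    "ArrangementSummary",
    "feature_length",
    "intergenic_gap",
    "build_arrangement",
    "summarize_arrangement",
    "gene_order_signature",
    "write_arrangement_report",
]


def feature_length(f: FeatureAnnotation, genome_length: int) -> int:
    """Feature size in bp; wrapped features count suffix + prefix."""
    if f.end > genome_length or f.start > genome_length:
        raise ValueError(f"feature {f.name!r} outside genome of length {genome_length}")
    if f.wraps:
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


def _linear_end(f: FeatureAnnotation) -> int:
    # For a wrapped feature the genomic end (past the origin) is the small coordinate.
    return f.end


def intergenic_gap(prev: FeatureAnnotation, next: FeatureAnnotation,
                   genome_length: int) -> int:
    """Signed gap ``next.start - prev.end - 1`` between circular neighbours.

    0 = abutting; negative = overlap length, negated.  When the adjacency
    crosses the origin the gap is taken modulo the circumference: a raw gap
    more negative than either feature could overlap is interpreted as a wrap.
    """
    if prev is next or (prev.name == next.name and prev.start == next.start
                        and prev.end == next.end):
        raise ValueError("intergenic gap of a feature with itself is undefined")
    gap = next.start - _linear_end(prev) - 1
    max_overlap = min(feature_length(prev, genome_length),
                      feature_length(next, genome_length))
    if gap < -max_overlap:
        gap += genome_length
    return gap


@dataclass(frozen=True)
class ArrangementRow:
    """One feature with its computed size and signed gap to the next feature."""

    name: str
    gene_class: GeneClass
    strand: str
    start: int
    end: int
    size: int
    ign_next: int
    printed_size: Optional[int] = None
    printed_ign: Optional[int] = None
    degenerate_adjacency: bool = False


@dataclass(frozen=True)
class ArrangementSummary:
    counts: dict[GeneClass, int]
    total_length: dict[GeneClass, int]
    spacer_count: int
    spacer_total: int
    spacer_max: int
    overlap_count: int
    overlap_total: int
    overlap_max: int
    pcg_fraction_of_genome: float


def build_arrangement(table: AnnotationTable) -> list[ArrangementRow]:
    """Circularly ordered rows with computed sizes and gaps.

    The last row's gap wraps to the first feature.  A single-feature circle
    gets ``ign_next = genome_length - size`` flagged as degenerate.
    """
    feats = table.features
    if not feats:
        raise ValueError("annotation table has no features")
    spans = [(f.start, f.end) for f in feats]
    if len(set(spans)) < len(spans):
        warnings.warn("annotation contains features with identical spans")

    n = len(feats)
    rows = []
    for i, f in enumerate(feats):
        size = feature_length(f, table.genome_length)
        if n == 1:
            gap = table.genome_length - size
            degenerate = True
        else:
            nxt = feats[(i + 1) % n]
            if i == n - 1 and not f.wraps:
                # explicit wrap adjacency back to the first feature
                gap = (nxt.start + table.genome_length) - f.end - 1
                if gap >= table.genome_length:
                    gap -= table.genome_length
            else:
                gap = intergenic_gap(f, nxt, table.genome_length)
            degenerate = False
        rows.append(
            ArrangementRow(
                name=f.name,
                gene_class=f.gene_class,
                strand=f.strand,
                start=f.start,
                end=f.end,
                size=size,
                ign_next=gap,
                printed_size=table.printed_sizes[i] if table.printed_sizes else None,
                printed_ign=table.ign[i] if table.ign else None,
                degenerate_adjacency=degenerate,
            )
        )
    return rows


def summarize_arrangement(
    rows: list[ArrangementRow],
    ign_source: str = "computed",
    size_source: str = "computed",
    genome_length: Optional[int] = None,
) -> ArrangementSummary:
    """Spacer/overlap statistics and per-class totals.

    ``ign_source``/``size_source`` select the coordinate-derived values or a
    verbatim printed column; spacers are strictly positive IGN values,
    overlaps strictly negative (absent printed cells are skipped).
    """
    for src, name in ((ign_source, "ign_source"), (size_source, "size_source")):
        if src not in ("computed", "printed"):
            raise ValueError(f"{name} must be 'computed' or 'printed', got {src!r}")

    if ign_source == "printed":
        if all(r.printed_ign is None for r in rows):
            raise ValueError("printed IGN requested but no printed column present")
        gaps = [r.printed_ign for r in rows if r.printed_ign is not None]
    else:
        gaps = [r.ign_next for r in rows]

    if size_source == "printed":
        if any(r.printed_size is None for r in rows):
            raise ValueError("printed sizes requested but column incomplete")
        sizes = [r.printed_size for r in rows]
    else:
        sizes = [r.size for r in rows]

    counts: dict[GeneClass, int] = {}
    totals: dict[GeneClass, int] = {}
    for r, size in zip(rows, sizes):
        counts[r.gene_class] = counts.get(r.gene_class, 0) + 1
        totals[r.gene_class] = totals.get(r.gene_class, 0) + size

    spacers = [g for g in gaps if g > 0]
    overlaps = [g for g in gaps if g < 0]
    if genome_length is None:
        # conservation of circumference: sizes + computed gaps tile the circle
        genome_length = sum(r.size + r.ign_next for r in rows)
    pcg_total = totals.get(GeneClass.PCG, 0)
    return ArrangementSummary(
        counts=counts,
        total_length=totals,
        spacer_count=len(spacers),
        spacer_total=sum(spacers),
        spacer_max=max(spacers, default=0),
        overlap_count=len(overlaps),
        overlap_total=sum(-g for g in overlaps),
        overlap_max=max((-g for g in overlaps), default=0),
        pcg_fraction_of_genome=round_half_up(100.0 * pcg_total / genome_length, 2),
    )


def gene_order_signature(table: AnnotationTable, anchor: str = "trnI") -> str:
    """Canonical rotation of ``name(strand)`` tokens.

    Rotation starts at ``anchor`` when present, else at the lexicographically
    minimal rotation; two genomes share an arrangement iff signatures match.
    """
    if not table.features:
        raise ValueError("annotation table has no features")
    tokens = [f"{f.name}({f.strand})" for f in table.features]
    names = [f.name for f in table.features]
    if anchor in names:
        i = names.index(anchor)
        rotated = tokens[i:] + tokens[:i]
    else:
        rotations = [tokens[i:] + tokens[:i] for i in range(len(tokens))]
        rotated = min(rotations)
    return " ".join(rotated)


def write_arrangement_report(table: AnnotationTable, path: str | Path) -> None:
    """TSV report: source-table columns plus computed_size and computed_ign."""
    rows = build_arrangement(table)
    header = FEATURE_TABLE_HEADER + ["computed_size", "computed_ign"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for f, r in zip(table.features, rows):
            fh.write(
                "\t".join(
                    [
                        f.name,
                        f.strand,
                        f"{f.start}-{f.end}",
                        "" if r.printed_size is None else str(r.printed_size),
                        f.anticodon or "",
                        f.start_codon or "",
                        f.stop_codon or "",
                        "" if r.printed_ign is None else str(r.printed_ign),
                        str(r.size),
                        str(r.ign_next),
                    ]
                )
                + "\n"
            )
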