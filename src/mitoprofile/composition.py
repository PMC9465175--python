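"""Base composition, A+T content, and strand skews.

AT skew = (A - T)/(A + T); GC skew = (G - C)/(G + C).  Some published
composition tables print the GC column with the opposite orientation,
(C - G)/(C + G), so the orientation is an explicit flag rather than a
hidden convention.

Percentages are computed over non-N positions; class rows concatenate the
strand-oriented (reading-strand) sequences of the class, since skew is
strand-dependent.  Unrounded values are carried internally; rounding
(percentages 2 decimals, skews 3, half-up) happens only at the report edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from ._round import round_half_up
from .annotation_io import (
    AnnotationTable,
    GeneClass,
    GenomeRecord,
    extract_feature_sequence,
)

__all__ = [
    "CompositionRow",
    "base_counts",
    "base_composition",
    "at_skew",
    "gc_skew",
    "composition_row",
    "composition_report",
    "write_composition_report",
    "COMPOSITION_HEADER",
]

COMPOSITION_HEADER = ["Feature", "A%", "C%", "G%", "T%", "A+T%", "A+T skew", "G+C skew"]

DEFAULT_CLASS_ROWS = [
    ("Whole genome", None),
    ("PCG", GeneClass.PCG),
    ("rRNA", GeneClass.RRNA),
    ("tRNA", GeneClass.TRNA),
    ("A+T region", GeneClass.CONTROL_REGION),
]


@dataclass(frozen=True)
class CompositionRow:
    """Unrounded composition of one labelled sequence (skews None when undefined)."""

    label: str
    pct_a: float
    pct_c: float
    pct_g: float
    pct_t: float
    pct_at: float
    at_skew: Optional[float]
    gc_skew: Optional[float]

    def rounded(self) -> list:
        """Report-edge values: percentages at 2 decimals, skews at 3."""
        return [
            self.label,
            *(round_half_up(p, 2) for p in (self.pct_a, self.pct_c, self.pct_g,
                                            self.pct_t, self.pct_at)),
            None if self.at_skew is None else round_half_up(self.at_skew, 3),
            None if self.gc_skew is None else round_half_up(self.gc_skew, 3),
        ]


def base_counts(seq: str) -> dict[str, int]:
    seq = seq.upper()
    return {b: seq.count(b) for b in "ACGTN"}


def base_composition(seq: str) -> tuple[float, float, float, float, float]:
    """(A%, C%, G%, T%, A+T%) over non-N positions, unrounded."""
    if not seq:
        raise ValueError("empty sequence")
    c = base_counts(seq)
    denom = c["A"] + c["C"] + c["G"] + c["T"]
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    pa, pc, pg, pt = (100.0 * c[b] / denom for b in "ACGT")
    return pa, pc, pg, pt, pa + pt


def at_skew(a: float, t: float) -> Optional[float]:
    """(a - t)/(a + t) from counts or percentages; None when a + t == 0."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float, orientation: str = "g_minus_c") -> Optional[float]:
    """(g - c)/(g + c) or (c - g)/(c + g); None when g + c == 0."""
    if orientation not in ("g_minus_c", "c_minus_g"):
        raise ValueError(f"unknown gc_skew orientation {orientation!r}")
    if g + c == 0:
        return None
    val = (g - c) / (g + c)
    return -val if orientation == "c_minus_g" else val


def composition_row(label: str, seq: str,
                    gc_orientation: str = "g_minus_c") -> CompositionRow:
    """Composition and skews of one sequence, computed at count level."""
    c = base_counts(seq)
    pa, pc, pg, pt, pat = base_composition(seq)
    return CompositionRow(
        label=label,
        pct_a=pa, pct_c=pc, pct_g=pg, pct_t=pt, pct_at=pat,
        at_skew=at_skew(c["A"], c["T"]),
        gc_skew=gc_skew(c["G"], c["C"], gc_orientation),
    )


def composition_report(
    genome: GenomeRecord,
    table: AnnotationTable,
    class_spec: Optional[list[tuple[str, Optional[GeneClass]]]] = None,
    gc_orientation: str = "g_minus_c",
) -> list[CompositionRow]:
    """Whole-genome and per-class composition rows.

    Class rows are computed over the concatenation of reading-strand feature
    sequences of the class; the whole-genome row over the plus strand.  Empty
    classes are skipped with a warning.
    """
    rows: list[CompositionRow] = []
    for label, gene_class in (class_spec or DEFAULT_CLASS_ROWS):
        if gene_class is None:
            seq = genome.seq
        else:
            feats = table.by_class(gene_class)
            if not feats:
                warnings.warn(f"no features of class {gene_class.value}; "
                              f"row {label!r} omitted")
                continue
            seq = "".join(extract_feature_sequence(genome, f) for f in feats)
        rows.append(composition_row(label, seq, gc_orientation))
    return rows


def write_composition_report(rows: list[CompositionRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COMPOSITION_HEADER) + "\n")
        for row in rows:
            vals = row.rounded()
            fh.write(
                "\t".join("" if v is None else (v if isinstance(v, str) else f"{v:g}")
                          for v in vals)
                + "\n"
            )
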