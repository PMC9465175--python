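"""Repeat-feature detection in the A+T-rich (control) region.

Three detectors, all maximal-by-construction and verified in the test suite
against naive quadratic oracles:

* homopolymer runs (e.g. the poly-T stretch and terminal poly-A element),
* dinucleotide-unit microsatellites (e.g. (TA)n), reported with the
  lexicographically least rotation of the unit so the TA/AT phase ambiguity
  resolves deterministically,
* long direct (same-strand) repeats: maximal substrings occurring at two or
  more positions, found by seeding on shared k-mers and extending with
  explicit character comparison (collision-proof), pairs contained in a
  longer duplicate being suppressed by the maximal extension itself.

Coordinates are region-relative and 1-based; genome-absolute starts are
added by :func:`region_report`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

from .annotation_io import AnnotationTable, GeneClass, GenomeRecord, extract_feature_sequence
from .composition import CompositionRow, composition_row

__all__ = [
    "RepeatFeature",
    "RegionParams",
    "RegionReport",
    "homopolymer_runs",
    "microsatellites",
    "long_direct_repeats",
    "region_report",
    "write_region_report",
]


@dataclass(frozen=True)
class RepeatFeature:
    """One detected repeat; ``length == copies * len(unit)`` for tandem kinds."""

    kind: str  # homopolymer | microsatellite | direct_repeat
    start: int  # region-relative, 1-based
    length: int
    unit: str
    copies: int
    mate_start: Optional[int] = None  # second occurrence (direct repeats)
    abs_start: Optional[int] = None  # genome-absolute start, filled by region_report


def homopolymer_runs(seq: str, min_len: int = 10) -> list[RepeatFeature]:
    """Maximal single-base runs of length >= min_len, left to right."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = seq.upper()
    out = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            out.append(
                RepeatFeature(
                    kind="homopolymer", start=i + 1, length=j - i,
                    unit=seq[i], copies=j - i,
                )
            )
        i = j
    return out


def _least_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def microsatellites(seq: str, unit_len: int = 2,
                    min_copies: int = 5) -> list[RepeatFeature]:
    """Maximal tandem arrays of a unit_len-bp unit with >= min_copies copies.

    Arrays are the maximal periodicity-``unit_len`` stretches, trimmed to
    whole copies, so every array is reported exactly once regardless of
    phase.  Arrays whose unit is a single repeated base are homopolymers,
    not microsatellites, and are excluded when unit_len > 1.
    """
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    seq = seq.upper()
    n = len(seq)
    out = []
    i = 0
    while i + unit_len < n:
        if seq[i + unit_len] != seq[i]:
            i += 1
            continue
        # maximal period-unit_len run starting at i
        j = i + unit_len
        while j < n and seq[j] == seq[j - unit_len]:
            j += 1
        span = j - i  # run of positions with period unit_len, plus seed unit
        copies = span // unit_len
        if copies >= min_copies:
            unit = seq[i : i + unit_len]
            if not (unit_len > 1 and len(set(unit)) == 1):
                out.append(
                    RepeatFeature(
                        kind="microsatellite",
                        start=i + 1,
                        length=copies * unit_len,
                        unit=_least_rotation(unit),
                        copies=copies,
                    )
                )
        i = j - unit_len + 1
    return out


def long_direct_repeats(seq: str, min_len: int = 30) -> list[RepeatFeature]:
    """Maximal repeated substrings of length >= min_len (>= 2 occurrences).

    Each maximal occurrence pair is reported once with both starts;
    overlapping occurrences are allowed.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    seq = seq.upper()
    n = len(seq)
    if n < 2 * 1:  # trivially short
        return []
    k = min_len
    kmers: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmers.setdefault(seq[i : i + k], []).append(i)
    found: set[tuple[int, int, int]] = set()
    for positions in kmers.values():
        if len(positions) < 2:
            continue
        for a_i in range(len(positions) - 1):
            for b_i in range(a_i + 1, len(positions)):
                i, j = positions[a_i], positions[b_i]
                # extend left
                li, lj = i, j
                while li > 0 and lj > 0 and seq[li - 1] == seq[lj - 1]:
                    li -= 1
                    lj -= 1
                # extend right
                ri, rj = i + k, j + k
                while ri < n and rj < n and seq[ri] == seq[rj]:
                    ri += 1
                    rj += 1
                found.add((li, lj, ri - li))
    out = [
        RepeatFeature(
            kind="direct_repeat",
            start=i + 1,
            length=length,
            unit=seq[i : i + length],
            copies=2,
            mate_start=j + 1,
        )
        for i, j, length in sorted(found)
    ]
    return out


@dataclass(frozen=True)
class RegionParams:
    """Detector minima (defaults match the features a control region shows)."""

    homopolymer_min: int = 10
    microsat_unit: int = 2
    microsat_min_copies: int = 5
    repeat_min: int = 30


@dataclass(frozen=True)
class RegionReport:
    region_name: str
    region_start: int
    region_end: int
    composition: CompositionRow
    features: tuple[RepeatFeature, ...]


def region_report(
    genome: GenomeRecord,
    table: AnnotationTable,
    params: RegionParams = RegionParams(),
    gc_orientation: str = "g_minus_c",
) -> RegionReport:
    """Run all three detectors plus a composition row on the control region."""
    regions = table.by_class(GeneClass.CONTROL_REGION)
    if not regions:
        raise ValueError("annotation contains no control-region feature")
    region = regions[0]
    seq = extract_feature_sequence(genome, region)
    feats: list[RepeatFeature] = []
    feats += homopolymer_runs(seq, params.homopolymer_min)
    feats += microsatellites(seq, params.microsat_unit, params.microsat_min_copies)
    feats += long_direct_repeats(seq, params.repeat_min)

    def absolute(rel_start: int) -> int:
        # region-relative positions refer to the reading strand; absolute
        # coordinates are reported for plus-strand regions directly
        if region.strand == "+" and not region.wraps:
            return region.start + rel_start - 1
        pos = region.start + rel_start - 1
        if pos > table.genome_length:
            pos -= table.genome_length
        return pos

    feats = [replace(f, abs_start=absolute(f.start)) for f in feats]
    feats.sort(key=lambda f: (f.start, f.kind, f.mate_start or 0))
    return RegionReport(
        region_name=region.name,
        region_start=region.start,
        region_end=region.end,
        composition=composition_row(region.name, seq, gc_orientation),
        features=tuple(feats),
    )


def write_region_report(report: RegionReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tstart\tlength\tunit\tcopies\tmate_start\tabs_start\n")
        for f in report.features:
            fh.write(
                "\t".join(
                    [
                        f.kind,
                        str(f.start),
                        str(f.length),
                        f.unit,
                        str(f.copies),
                        "" if f.mate_start is None else str(f.mate_start),
                        "" if f.abs_start is None else str(f.abs_start),
                    ]
                )
                + "\n"
            )
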