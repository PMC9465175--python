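"""Circular-genome data model and annotation I/O.

All coordinates are 1-based inclusive, the convention of published mitogenome
annotation tables.  A feature whose ``start`` exceeds its ``end`` wraps the
circular origin; wrap arithmetic always requires the genome length.

Standard formats (FASTA, GenBank flat files) are read and written through
Biopython; the tab-separated feature-table dialect mirrors the column layout
of published annotation tables (Gene / Direction / Location / Size (bp) /
Anticodon / Start codon / Stop codon / Intergenic Nucleotides).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneClass",
    "PLUS",
    "MINUS",
    "GenomeRecord",
    "FeatureAnnotation",
    "AnnotationTable",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "write_genbank",
    "extract_feature_sequence",
    "extract_span",
    "reverse_complement",
]

PLUS = "+"
MINUS = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")

FEATURE_TABLE_HEADER = [
    "Gene",
    "Direction",
    "Location",
    "Size (bp)",
    "Anticodon",
    "Start codon",
    "Stop codon",
    "Intergenic Nucleotides *",
]


class GeneClass(str, Enum):
    """Functional class of an annotated mitogenome feature."""

    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL_REGION = "control_region"


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence, by default circular.

    ``seq`` is upper-case over {A,C,G,T,N}; ``length`` is always
    ``len(seq)`` and must be positive.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = next((i for i, b in enumerate(self.seq) if b not in _VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"genome {self.id!r}: invalid character {self.seq[bad]!r} "
                f"at position {bad + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature with 1-based inclusive coordinates.

    ``start > end`` encodes a feature wrapping the circular origin.
    """

    name: str
    gene_class: GeneClass
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"feature {self.name!r}: coordinates must be >= 1")

    @property
    def wraps(self) -> bool:
        return self.start > self.end


@dataclass
class AnnotationTable:
    """Ordered annotation of one genome.

    ``ign`` and ``printed_sizes``, when present, preserve verbatim the
    intergenic-nucleotide and size columns of a source table (which may
    disagree with the coordinates); ``None`` entries mark absent cells.
    """

    genome_id: str
    genome_length: int
    features: list[FeatureAnnotation]
    ign: Optional[list[Optional[int]]] = None
    printed_sizes: Optional[list[Optional[int]]] = None

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate feature names: {sorted(dup)}")
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.name!r} ({f.start}..{f.end}) exceeds genome "
                    f"length {self.genome_length}"
                )
        for attr in ("ign", "printed_sizes"):
            col = getattr(self, attr)
            if col is not None and len(col) != len(self.features):
                raise ValueError(
                    f"{attr} column has {len(col)} entries for "
                    f"{len(self.features)} features"
                )

    def feature(self, name: str) -> FeatureAnnotation:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def by_class(self, gene_class: GeneClass) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.gene_class == gene_class]


# ---------------------------------------------------------------------------
# FASTA


def _normalize_sequence(raw: str, label: str) -> str:
    seq = str(raw).upper().replace("U", "T")
    bad = next((i for i, b in enumerate(seq) if b not in _VALID_BASES), None)
    if bad is not None:
        raise ValueError(
            f"record {label!r}: non-IUPAC character {seq[bad]!r} at position {bad + 1}"
        )
    return seq


def read_fasta(path: str | Path, circular: bool = True) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are upper-cased and U is mapped to T; input order is preserved.
    """
    records = [
        GenomeRecord(id=rec.id, seq=_normalize_sequence(rec.seq, rec.id), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature-table dialect

_LOCATION_RE = re.compile(r"^\s*([\d,]+)\s*[–—-]\s*([\d,]+)\s*$")
_ABSENT_CELLS = {"", "-", "–", "—"}


def _parse_int_cell(cell: str) -> Optional[int]:
    cell = cell.strip().replace(",", "").replace("−", "-")
    if cell in _ABSENT_CELLS:
        return None
    return int(cell)


def infer_gene_class(name: str) -> GeneClass:
    """Classify a feature from its conventional mitogenome gene name."""
    low = name.lower()
    if low.startswith("trn"):
        return GeneClass.TRNA
    if low.startswith("rrn"):
        return GeneClass.RRNA
    if "rich" in low or "control" in low or "d-loop" in low or low in {"cr", "at_rich"}:
        return GeneClass.CONTROL_REGION
    return GeneClass.PCG


def _parse_strand_cell(cell: str) -> str:
    cell = cell.strip()
    if cell in {"-", "−"}:
        return MINUS
    # em-dash or blank: unspecified, defaults to the majority strand
    if cell in {"+", "", "–", "—"}:
        return PLUS
    raise ValueError(f"unrecognised direction cell {cell!r}")


def read_feature_table(path: str | Path, genome_length: int,
                       genome_id: str = "") -> AnnotationTable:
    """Read the tab-separated annotation dialect.

    Locations accept hyphen, en-dash or em-dash separators and thousands
    separators ("14,596–16060"); em-dash/blank cells are absent.  The printed
    Size and Intergenic Nucleotides columns are retained verbatim.
    """
    lines = Path(path).read_text().splitlines()
    rows = [ln.split("\t") for ln in lines if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty feature table")
    header = [c.strip() for c in rows[0]]
    required = ["Gene", "Direction", "Location"]
    col = {}
    for want in ["Gene", "Direction", "Location", "Size", "Anticodon",
                 "Start codon", "Stop codon", "Intergenic"]:
        idx = next((i for i, h in enumerate(header) if h.startswith(want)), None)
        col[want] = idx
        if want in required and idx is None:
            raise ValueError(f"{path}: missing required column {want!r}")

    def cell(row: list[str], key: str) -> str:
        i = col[key]
        return row[i].strip() if i is not None and i < len(row) else ""

    features: list[FeatureAnnotation] = []
    ign: list[Optional[int]] = []
    sizes: list[Optional[int]] = []
    seen: set[str] = set()
    for row in rows[1:]:
        name = cell(row, "Gene").strip("*").strip()
        if not name:
            raise ValueError(f"{path}: row with empty gene name: {row!r}")
        if name in seen:
            raise ValueError(f"{path}: duplicate gene name {name!r}")
        seen.add(name)
        m = _LOCATION_RE.match(cell(row, "Location"))
        if m is None:
            raise ValueError(
                f"{path}: unparseable location {cell(row, 'Location')!r} "
                f"in row {name!r}"
            )
        start = int(m.group(1).replace(",", ""))
        end = int(m.group(2).replace(",", ""))
        anticodon = cell(row, "Anticodon")
        start_codon = cell(row, "Start codon")
        stop_codon = cell(row, "Stop codon")
        features.append(
            FeatureAnnotation(
                name=name,
                gene_class=infer_gene_class(name),
                strand=_parse_strand_cell(cell(row, "Direction")),
                start=start,
                end=end,
                anticodon=anticodon if anticodon not in _ABSENT_CELLS else None,
                start_codon=start_codon if start_codon not in _ABSENT_CELLS else None,
                stop_codon=stop_codon if stop_codon not in _ABSENT_CELLS else None,
            )
        )
        sizes.append(_parse_int_cell(cell(row, "Size")) if col["Size"] is not None else None)
        ign.append(_parse_int_cell(cell(row, "Intergenic")) if col["Intergenic"] is not None else None)

    return AnnotationTable(
        genome_id=genome_id,
        genome_length=genome_length,
        features=features,
        ign=ign if any(v is not None for v in ign) else None,
        printed_sizes=sizes if any(v is not None for v in sizes) else None,
    )


def write_feature_table(table: AnnotationTable, path: str | Path) -> None:
    """Write the tab-separated annotation dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TABLE_HEADER) + "\n")
        for i, f in enumerate(table.features):
            size = table.printed_sizes[i] if table.printed_sizes else None
            ign = table.ign[i] if table.ign else None
            fh.write(
                "\t".join(
                    [
                        f.name,
                        f.strand,
                        f"{f.start}-{f.end}",
                        "" if size is None else str(size),
                        f.anticodon or "",
                        f.start_codon or "",
                        f.stop_codon or "",
                        "" if ign is None else str(ign),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GenBank flat files

_GB_CLASS_BY_TYPE = {
    "CDS": GeneClass.PCG,
    "tRNA": GeneClass.TRNA,
    "rRNA": GeneClass.RRNA,
    "misc_feature": GeneClass.CONTROL_REGION,
    "D-loop": GeneClass.CONTROL_REGION,
}

_GB_TYPE_BY_CLASS = {
    GeneClass.PCG: "CDS",
    GeneClass.TRNA: "tRNA",
    GeneClass.RRNA: "rRNA",
    GeneClass.CONTROL_REGION: "D-loop",
}


def read_genbank(path: str | Path) -> tuple[GenomeRecord, AnnotationTable]:
    """Read a GenBank flat file (LOCUS, FEATURES, ORIGIN subset).

    ``complement(a..b)`` maps to the minus strand; a ``join`` spanning the
    origin maps to a wrapped feature (start > end).
    """
    rec = SeqIO.read(str(path), "genbank")
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: missing or empty ORIGIN block")
    seq = _normalize_sequence(rec.seq, rec.id)
    circular = rec.annotations.get("topology", "circular") == "circular"
    genome = GenomeRecord(id=rec.id, seq=seq, circular=circular)

    features: list[FeatureAnnotation] = []
    seen: set[str] = set()
    for ft in rec.features:
        if ft.type not in _GB_CLASS_BY_TYPE:
            continue
        quals = ft.qualifiers
        name = (quals.get("gene") or quals.get("product") or [ft.type])[0]
        if name in seen:  # keep names unique for the table invariant
            k = 2
            while f"{name}_{k}" in seen:
                k += 1
            name = f"{name}_{k}"
        seen.add(name)
        loc = ft.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # origin-spanning join: [a..L] + [1..b]
            start = int(parts[-1].start) + 1
            end = int(parts[0].end)
        else:
            start = int(loc.start) + 1
            end = int(loc.end)
            if end > genome.length:
                raise ValueError(
                    f"{path}: feature {name!r} extends beyond LOCUS length"
                )
        strand = MINUS if loc.strand == -1 else PLUS
        anticodon = quals.get("anticodon", [None])[0]
        features.append(
            FeatureAnnotation(
                name=name,
                gene_class=_GB_CLASS_BY_TYPE[ft.type],
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
            )
        )
    features.sort(key=lambda f: (f.start, f.end))
    return genome, AnnotationTable(
        genome_id=genome.id, genome_length=genome.length, features=features
    )


def write_genbank(genome: GenomeRecord, table: AnnotationTable, path: str | Path) -> None:
    """Write genome + annotation as a GenBank flat file (round-trips with the reader)."""
    rec = SeqRecord(
        Seq(genome.seq),
        id=genome.id,
        name=re.sub(r"\W", "_", genome.id)[:16] or "genome",
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in table.features:
        strand = -1 if f.strand == MINUS else 1
        if f.wraps:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, genome.length, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        rec.features.append(
            SeqFeature(loc, type=_GB_TYPE_BY_CLASS[f.gene_class], qualifiers=quals)
        )
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_span(genome: GenomeRecord, start: int, end: int, strand: str = PLUS) -> str:
    """Extract 1-based inclusive ``start..end``; ``start > end`` wraps the origin."""
    if start < 1 or end < 1 or start > genome.length or end > genome.length:
        raise ValueError(
            f"span {start}..{end} outside genome of length {genome.length}"
        )
    if start > end:
        if not genome.circular:
            raise ValueError(
                f"span {start}..{end} wraps the origin of a non-circular genome"
            )
        seq = genome.seq[start - 1 :] + genome.seq[:end]
    else:
        seq = genome.seq[start - 1 : end]
    return reverse_complement(seq) if strand == MINUS else seq


def extract_feature_sequence(genome: GenomeRecord, f: FeatureAnnotation) -> str:
    """Feature sequence on its reading strand (minus features reverse-complemented)."""
    return extract_span(genome, f.start, f.end, f.strand)
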