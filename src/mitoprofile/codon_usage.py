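"""Codon counting, RSCU, codons-per-thousand, and terminal-codon classification.

RSCU (relative synonymous codon usage) for codon *c* in synonymous family *f*
is ``count(c) * degeneracy(f) / sum of counts over f``; codons-per-thousand
(CDspT) is ``1000 * group count / total``.

The synonymous-family partition follows a genetic code.  Two partitions ship:
the standard code (Ser 6-fold UCN+AGY, Arg 6-fold CGN+AGR, AUA in 3-fold Ile,
UGA in the stop family) and the invertebrate mitochondrial code (AGR -> Ser,
AUA -> Met, UGA -> Trp).  Mitochondrial codon-usage tables are sometimes
labelled with one code but computed under the other, so the partition is an
explicit parameter and every report names the one used.

Codon counts are keyed by RNA codons (UUA, not TTA); inputs in either
alphabet are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Data import CodonTable

from ._round import round_half_up

__all__ = [
    "ALL_CODONS",
    "NAMED_GROUPS",
    "GeneticCodePartition",
    "genetic_code_partition",
    "CodonExtraction",
    "CodonUsageTable",
    "TerminalCall",
    "extract_codons",
    "count_codons",
    "rscu",
    "cdspt",
    "classify_terminals",
    "write_codon_report_long",
    "write_codon_report_wide",
]

_RNA = str.maketrans("Tt", "Uu")
_DNA = str.maketrans("Uu", "Tt")

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in product("UCAG", repeat=3)
)

#: Two-fold/four-fold split groups used when discussing six-fold families:
#: Leu2/Ser1/Arg2 are the two-codon halves, Leu1/Ser2/Arg1 the four-codon ones.
NAMED_GROUPS: dict[str, frozenset[str]] = {
    "Leu1": frozenset({"CUU", "CUC", "CUA", "CUG"}),
    "Leu2": frozenset({"UUA", "UUG"}),
    "Ser1": frozenset({"AGU", "AGC"}),
    "Ser2": frozenset({"UCU", "UCC", "UCA", "UCG"}),
    "Arg1": frozenset({"CGU", "CGC", "CGA", "CGG"}),
    "Arg2": frozenset({"AGA", "AGG"}),
}

STOP_FAMILY = "*"

_CODE_IDS = {"standard": 1, "invertebrate_mito": 5}


def as_rna(codon: str) -> str:
    return codon.upper().translate(_RNA)


def as_dna(codon: str) -> str:
    return codon.upper().translate(_DNA)


@dataclass(frozen=True)
class GeneticCodePartition:
    """Partition of the 64 codons into synonymous families under one code."""

    code_name: str
    family_of: Mapping[str, str]  # RNA codon -> family id (aa letter or '*')
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.family_of) != set(ALL_CODONS):
            raise ValueError("family map must cover exactly the 64 codons")

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            out.setdefault(self.family_of[codon], []).append(codon)
        return {fam: tuple(cods) for fam, cods in out.items()}

    def degeneracy(self, family: str) -> int:
        return len(self.families[family])


def genetic_code_partition(name: str = "standard") -> GeneticCodePartition:
    """Build a partition from a named genetic code ('standard' | 'invertebrate_mito')."""
    if name not in _CODE_IDS:
        raise ValueError(
            f"unknown genetic code {name!r}; expected one of {sorted(_CODE_IDS)}"
        )
    table = CodonTable.unambiguous_dna_by_id[_CODE_IDS[name]]
    family_of = {as_rna(c): aa for c, aa in table.forward_table.items()}
    for c in table.stop_codons:
        family_of[as_rna(c)] = STOP_FAMILY
    return GeneticCodePartition(
        code_name=name,
        family_of=family_of,
        start_codons=frozenset(as_rna(c) for c in table.start_codons),
    )


@dataclass(frozen=True)
class CodonExtraction:
    """Codons of one CDS plus its trailing partial codon and N-containing tally."""

    codons: tuple[str, ...]
    trailing: str  # 0-2 nt left over (incomplete stop)
    n_excluded: int  # codons dropped because they contain N


def extract_codons(cds: str, frame_policy: str = "from_start") -> CodonExtraction:
    """Consecutive non-overlapping triplets from position 1.

    The trailing 1-2 nt (an incomplete stop completed by polyadenylation) is
    recorded, and codons containing N are excluded with a tally.
    """
    if frame_policy != "from_start":
        raise ValueError(f"unknown frame_policy {frame_policy!r}")
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError(f"CDS of length {len(cds)} is shorter than one codon")
    n_full = len(cds) // 3
    codons = []
    n_excluded = 0
    for i in range(n_full):
        codon = cds[3 * i : 3 * i + 3]
        if "N" in codon:
            n_excluded += 1
        else:
            codons.append(codon)
    return CodonExtraction(
        codons=tuple(codons),
        trailing=cds[3 * n_full :],
        n_excluded=n_excluded,
    )


@dataclass
class CodonUsageTable:
    """Codon counts with optionally attached RSCU and per-thousand values."""

    counts: dict[str, int]  # RNA codon -> count, all 64 keys present
    total: int
    n_excluded: int = 0
    rscu: Optional[dict[str, float]] = None
    cdspt: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")


def _normalize_counts(counts: Mapping[str, int]) -> dict[str, int]:
    out = {c: 0 for c in ALL_CODONS}
    for codon, n in counts.items():
        key = as_rna(codon)
        if key not in out:
            raise ValueError(f"not a codon: {codon!r}")
        if n < 0:
            raise ValueError(f"negative count for {codon!r}")
        out[key] += int(n)
    return out


def count_codons(cds_list: Iterable[str]) -> CodonUsageTable:
    """Sum codon counts over CDS sequences given in reading orientation."""
    cds_list = list(cds_list)
    if not cds_list:
        raise ValueError("no CDS sequences given")
    counts = {c: 0 for c in ALL_CODONS}
    excluded = 0
    for cds in cds_list:
        ext = extract_codons(cds)
        excluded += ext.n_excluded
        for codon in ext.codons:
            counts[as_rna(codon)] += 1
    return CodonUsageTable(counts=counts, total=sum(counts.values()),
                           n_excluded=excluded)


def rscu(counts: Mapping[str, int],
         partition: GeneticCodePartition) -> dict[str, float]:
    """Unrounded RSCU per codon; codons of zero-total families are absent."""
    counts = _normalize_counts(counts)
    out: dict[str, float] = {}
    for family, codons in partition.families.items():
        fam_total = sum(counts[c] for c in codons)
        if fam_total == 0:
            continue
        k = len(codons)
        for c in codons:
            out[c] = counts[c] * k / fam_total
    return out


def cdspt(
    counts: Mapping[str, int],
    grouping: Union[str, Mapping[str, Iterable[str]]] = "codon",
    partition: Optional[GeneticCodePartition] = None,
) -> dict[str, float]:
    """Per-thousand frequencies, unrounded.

    ``grouping`` is ``"codon"`` (one value per codon), ``"family"`` (per
    synonymous family of ``partition``), or a mapping of group name to codon
    set (e.g. :data:`NAMED_GROUPS`).
    """
    counts = _normalize_counts(counts)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot compute per-thousand values of an empty table")
    if grouping == "codon":
        groups: Mapping[str, Iterable[str]] = {c: (c,) for c in ALL_CODONS}
    elif grouping == "family":
        if partition is None:
            raise ValueError("family grouping requires a partition")
        groups = partition.families
    else:
        groups = {name: tuple(as_rna(c) for c in cods)
                  for name, cods in grouping.items()}
    return {
        name: 1000.0 * sum(counts[c] for c in cods) / total
        for name, cods in groups.items()
    }


@dataclass(frozen=True)
class TerminalCall:
    """Start/stop classification of one CDS."""

    name: str
    start_codon: str
    is_atn: bool
    stop_codon: Optional[str]  # 'TAA'/'TAG', or partial 'T'/'TA', or None
    stop_complete: bool


def classify_terminals(
    cds_list: Sequence[tuple[str, str]],
    partition: Optional[GeneticCodePartition] = None,
) -> list[TerminalCall]:
    """Classify start and stop codons of named CDS (trailing partial included).

    A length divisible by 3 whose final triplet is a stop codon of the
    partition is a complete stop; a trailing remainder of 'T' or 'TA' is a
    partial stop completed to UAA by transcript polyadenylation.
    """
    partition = partition or genetic_code_partition("invertebrate_mito")
    stops_dna = {as_dna(c) for c, fam in partition.family_of.items()
                 if fam == STOP_FAMILY}
    out = []
    for name, seq in cds_list:
        seq = as_dna(seq.upper())
        if len(seq) < 3:
            raise ValueError(f"CDS {name!r} shorter than one codon")
        start = seq[:3]
        rem = len(seq) % 3
        stop: Optional[str] = None
        complete = False
        if rem == 0:
            last = seq[-3:]
            if last in stops_dna:
                stop, complete = last, True
        elif rem == 1 and seq[-1] == "T":
            stop = "T"
        elif rem == 2 and seq[-2:] == "TA":
            stop = "TA"
        out.append(
            TerminalCall(
                name=name,
                start_codon=start,
                is_atn=start.startswith("AT"),
                stop_codon=stop,
                stop_complete=complete,
            )
        )
    return out


def without_stops(table: CodonUsageTable,
                  partition: GeneticCodePartition) -> CodonUsageTable:
    """Copy of a usage table with the partition's stop-family codons zeroed.

    Stop codons are counted by default (reference usage tables include
    them); this flag-style helper removes them for analyses that want
    sense codons only.
    """
    counts = {
        c: (0 if partition.family_of[c] == STOP_FAMILY else n)
        for c, n in table.counts.items()
    }
    return CodonUsageTable(counts=counts, total=sum(counts.values()),
                           n_excluded=table.n_excluded)


# ---------------------------------------------------------------------------
# Reports


def _aa_label(partition: GeneticCodePartition, codon: str) -> str:
    fam = partition.family_of[codon]
    return "" if fam == STOP_FAMILY else fam


def write_codon_report_long(table: CodonUsageTable,
                            partition: GeneticCodePartition,
                            path: str | Path) -> None:
    """Long-format TSV: codon, aa, count, rscu, cdspt (rounded at the edge)."""
    rscu_vals = rscu(table.counts, partition)
    per_thousand = cdspt(table.counts, "codon")
    with open(path, "w") as fh:
        fh.write(f"# genetic_code: {partition.code_name}\n")
        fh.write("codon\taa\tcount\trscu\tcdspt\n")
        for codon in ALL_CODONS:
            r = rscu_vals.get(codon)
            fh.write(
                "\t".join(
                    [
                        codon,
                        _aa_label(partition, codon) or "*",
                        str(table.counts[codon]),
                        "" if r is None else f"{round_half_up(r, 2):.2f}",
                        f"{round_half_up(per_thousand[codon], 1):.1f}",
                    ]
                )
                + "\n"
            )


def write_codon_report_wide(table: CodonUsageTable,
                            partition: GeneticCodePartition,
                            path: str | Path) -> None:
    """Four-column-group TSV (Codon(aa), No., RSCU) in UCAG order."""
    rscu_vals = rscu(table.counts, partition)
    with open(path, "w") as fh:
        fh.write(f"# genetic_code: {partition.code_name}\n")
        fh.write("\t".join(["Codon(aa)", "No.", "RSCU"] * 4) + "\n")
        # 16 rows: first base/third base vary down, second base across
        for b1 in "UCAG":
            for b3 in "UCAG":
                cells = []
                for b2 in "UCAG":
                    codon = b1 + b2 + b3
                    aa = _aa_label(partition, codon)
                    label = f"{codon}({aa})" if aa else codon
                    r = rscu_vals.get(codon)
                    cells += [
                        label,
                        str(table.counts[codon]),
                        "" if r is None else f"{round_half_up(r, 2):.2f}",
                    ]
                fh.write("\t".join(cells) + "\n")
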