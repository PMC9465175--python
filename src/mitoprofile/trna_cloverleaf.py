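"""Heuristic cloverleaf folding of mitochondrial tRNA sequences.

The goal is arm-presence and base-pair-class inventories (which arms exist,
how many Watson-Crick / G·U wobble / mismatched stem pairs), not free
energies, so the search is an auditable anchored heuristic rather than
thermodynamic folding:

1. enumerate candidate anticodon arms — stems of 4-5 pairs enclosing a 7-nt
   loop, with the expected anticodon required at loop positions 3-5 when one
   is given (mitochondrial tRNAs keep the anticodon centred even when other
   arms degenerate);
2. fix the acceptor stem as the best pairing of the 5' 1-7 region against
   the 3' end (7 pairs, up to 2 non-pairs, allowing 0-2 unpaired trailing
   nucleotides for the discriminator);
3. search the DHU arm (stem 3-4, loop 4-12) between acceptor and anticodon
   arms and the T-arm (stem 4-5, loop 3-9) between anticodon arm and the
   acceptor 3' side;
4. score 3*WC + 2*GU - 1*mismatch over all stems and keep the best
   non-crossing assembly, ties broken leftmost-then-longest.

An arm with no stem meeting the minima is reported absent — exactly the
situation of mitochondrial tRNAs that have lost the T-arm or DHU arm.
All positions in the output are 1-based within the tRNA sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .annotation_io import AnnotationTable, GeneClass, GenomeRecord, extract_feature_sequence

__all__ = [
    "FoldParams",
    "Arm",
    "CloverleafStructure",
    "pair_class",
    "fold_cloverleaf",
    "classify_pairs",
    "fold_all",
    "dot_bracket",
    "write_structure_report",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pair_class(b1: str, b2: str) -> str:
    """'watson_crick', 'gu_wobble' or 'mismatch' for one stem pair (DNA alphabet)."""
    p = (b1.upper().replace("U", "T"), b2.upper().replace("U", "T"))
    if p in _WC:
        return "watson_crick"
    if p in _GU:
        return "gu_wobble"
    return "mismatch"


@dataclass(frozen=True)
class FoldParams:
    """Search thresholds and scoring weights (all configurable)."""

    anticodon_stem: tuple[int, int] = (4, 5)
    anticodon_loop: int = 7
    acceptor_pairs: int = 7
    acceptor_max_nonpairs: int = 2
    acceptor_trailing: tuple[int, ...] = (0, 1, 2)
    dhu_stem: tuple[int, int] = (3, 4)
    dhu_loop: tuple[int, int] = (4, 12)
    t_stem: tuple[int, int] = (4, 5)
    t_loop: tuple[int, int] = (3, 9)
    stem_max_mismatch: int = 1
    w_wc: int = 3
    w_gu: int = 2
    w_mismatch: int = -1
    min_length: int = 55
    max_length: int = 95


@dataclass(frozen=True)
class Arm:
    """One arm: nested stem pairs plus the enclosed loop span (1-based)."""

    stem_pairs: tuple[tuple[int, int], ...]
    loop_span: Optional[tuple[int, int]]
    present: bool

    @staticmethod
    def absent() -> "Arm":
        return Arm(stem_pairs=(), loop_span=None, present=False)


@dataclass(frozen=True)
class CloverleafStructure:
    acceptor: Arm
    dhu: Arm
    anticodon_arm: Arm
    anticodon: Optional[str]
    variable_loop: Optional[tuple[int, int]]
    tpsic: Arm
    pairs_classified: dict[str, int]
    mismatch_list: tuple[tuple[int, int, str], ...]
    score: int
    diagnostic: Optional[str] = None

    @property
    def arms_present(self) -> dict[str, bool]:
        return {
            "acceptor": self.acceptor.present,
            "dhu": self.dhu.present,
            "anticodon": self.anticodon_arm.present,
            "tpsic": self.tpsic.present,
        }


def _score_pairs(seq: str, pairs: list[tuple[int, int]], p: FoldParams) -> tuple[int, int]:
    """(score, mismatches) over 0-based pair indices."""
    score = mm = 0
    for i, j in pairs:
        cls = pair_class(seq[i], seq[j])
        if cls == "watson_crick":
            score += p.w_wc
        elif cls == "gu_wobble":
            score += p.w_gu
        else:
            score += p.w_mismatch
            mm += 1
    return score, mm


def _hairpin_pairs(start: int, stem: int, loop: int) -> list[tuple[int, int]]:
    """0-based pairs of a hairpin with given 5' start, stem length and loop length."""
    end = start + 2 * stem + loop - 1
    return [(start + k, end - k) for k in range(stem)]


def _best_arm(seq: str, lo: int, hi: int, stem_range: tuple[int, int],
              loop_range: tuple[int, int], p: FoldParams):
    """Best-scoring hairpin fully inside [lo, hi] (0-based inclusive), or None.

    Ties: leftmost start, then longest stem, then longest loop.
    """
    best = None
    for start in range(lo, hi + 1):
        for stem in range(stem_range[1], stem_range[0] - 1, -1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                end = start + 2 * stem + loop - 1
                if end > hi:
                    continue
                pairs = _hairpin_pairs(start, stem, loop)
                score, mm = _score_pairs(seq, pairs, p)
                if mm > p.stem_max_mismatch:
                    continue
                key = (-score, start, -stem, -loop)
                if best is None or key < best[0]:
                    best = (key, start, stem, loop, pairs, score)
    return best


def _acceptor_candidates(seq: str, p: FoldParams):
    """Acceptor-stem candidates per trailing offset: (offset, pairs, score, nonpairs)."""
    n = len(seq)
    out = []
    for t in p.acceptor_trailing:
        pairs = [(k, n - 1 - t - k) for k in range(p.acceptor_pairs)]
        if pairs[-1][1] <= pairs[-1][0]:
            continue
        score, _ = _score_pairs(seq, pairs, p)
        nonpairs = sum(
            1 for i, j in pairs if pair_class(seq[i], seq[j]) == "mismatch"
        )
        out.append((t, pairs, score, nonpairs))
    return out


def fold_cloverleaf(
    seq: str,
    expected_anticodon: Optional[str] = None,
    params: FoldParams = FoldParams(),
) -> CloverleafStructure:
    """Fold one tRNA sequence into its best-scoring cloverleaf assembly."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    p = params
    if n < p.min_length or n > p.max_length:
        warnings.warn(
            f"tRNA length {n} outside the expected {p.min_length}-{p.max_length} range"
        )
    anticodon_dna = (
        expected_anticodon.upper().replace("U", "T") if expected_anticodon else None
    )

    # candidate anticodon arms
    ac_candidates = []
    for start in range(0, n):
        for stem in range(p.anticodon_stem[1], p.anticodon_stem[0] - 1, -1):
            end = start + 2 * stem + p.anticodon_loop - 1
            if end >= n:
                continue
            loop_start = start + stem
            if anticodon_dna is not None:
                if seq[loop_start + 2 : loop_start + 5] != anticodon_dna:
                    continue
            pairs = _hairpin_pairs(start, stem, p.anticodon_loop)
            score, mm = _score_pairs(seq, pairs, p)
            if mm > p.stem_max_mismatch:
                continue
            ac_candidates.append((start, stem, pairs, score))

    if not ac_candidates:
        return CloverleafStructure(
            acceptor=Arm.absent(),
            dhu=Arm.absent(),
            anticodon_arm=Arm.absent(),
            anticodon=None,
            variable_loop=None,
            tpsic=Arm.absent(),
            pairs_classified={"watson_crick": 0, "gu_wobble": 0, "mismatch": 0},
            mismatch_list=(),
            score=0,
            diagnostic="no anticodon-arm candidate met the stem/loop minima",
        )

    acceptors = _acceptor_candidates(seq, p)

    best_assembly = None
    for ac_start, ac_stem, ac_pairs, ac_score in ac_candidates:
        ac_end = ac_start + 2 * ac_stem + p.anticodon_loop - 1
        for t, acc_pairs, acc_score, nonpairs in acceptors:
            acc_ok = nonpairs <= p.acceptor_max_nonpairs
            acc5_end = p.acceptor_pairs - 1  # 0-based end of the 5' acceptor side
            acc3_start = n - t - p.acceptor_pairs  # 0-based start of the 3' side
            if ac_start <= acc5_end + 1 or ac_end >= acc3_start:
                continue
            use_acc_score = acc_score if acc_ok else 0

            dhu = _best_arm(seq, acc5_end + 1, ac_start - 1, p.dhu_stem, p.dhu_loop, p)
            tps = _best_arm(seq, ac_end + 1, acc3_start - 1, p.t_stem, p.t_loop, p)
            total = (
                use_acc_score
                + ac_score
                + (dhu[5] if dhu else 0)
                + (tps[5] if tps else 0)
            )
            key = (-total, ac_start, -ac_stem, t)
            if best_assembly is None or key < best_assembly[0]:
                best_assembly = (key, ac_start, ac_stem, ac_pairs, t, acc_pairs,
                                 acc_ok, dhu, tps)

    (_, ac_start, ac_stem, ac_pairs, t, acc_pairs, acc_ok, dhu, tps) = best_assembly
    ac_end = ac_start + 2 * ac_stem + p.anticodon_loop - 1
    loop_start = ac_start + ac_stem

    def to_arm(pairs0, loop0) -> Arm:
        return Arm(
            stem_pairs=tuple((i + 1, j + 1) for i, j in pairs0),
            loop_span=None if loop0 is None else (loop0[0] + 1, loop0[1] + 1),
            present=True,
        )

    acceptor = (
        Arm(stem_pairs=tuple((i + 1, j + 1) for i, j in acc_pairs),
            loop_span=None, present=True)
        if acc_ok
        else Arm.absent()
    )
    anticodon_arm = to_arm(ac_pairs, (loop_start, loop_start + p.anticodon_loop - 1))
    anticodon = seq[loop_start + 2 : loop_start + 5]

    if dhu is not None:
        _, d_start, d_stem, d_loop, d_pairs, _ = dhu
        dhu_arm = to_arm(d_pairs, (d_start + d_stem, d_start + d_stem + d_loop - 1))
    else:
        dhu_arm = Arm.absent()

    if tps is not None:
        _, t_start, t_stem_len, t_loop_len, t_pairs, _ = tps
        tps_arm = to_arm(t_pairs, (t_start + t_stem_len,
                                   t_start + t_stem_len + t_loop_len - 1))
        var_span0 = (ac_end + 1, t_start - 1)
    else:
        tps_arm = Arm.absent()
        var_span0 = (ac_end + 1, n - t - p.acceptor_pairs - 1)
    variable_loop = (
        (var_span0[0] + 1, var_span0[1] + 1) if var_span0[0] <= var_span0[1] else None
    )

    structure = CloverleafStructure(
        acceptor=acceptor,
        dhu=dhu_arm,
        anticodon_arm=anticodon_arm,
        anticodon=anticodon,
        variable_loop=variable_loop,
        tpsic=tps_arm,
        pairs_classified={},
        mismatch_list=(),
        score=-best_assembly[0][0],
    )
    counts, mismatches = classify_pairs(structure, seq)
    return CloverleafStructure(
        **{
            **structure.__dict__,
            "pairs_classified": counts,
            "mismatch_list": tuple(mismatches),
        }
    )


def classify_pairs(structure: CloverleafStructure,
                   seq: str) -> tuple[dict[str, int], list[tuple[int, int, str]]]:
    """Count WC / G·U wobble / mismatch pairs over all stems; list mismatches."""
    seq = seq.upper().replace("U", "T")
    counts = {"watson_crick": 0, "gu_wobble": 0, "mismatch": 0}
    mismatches: list[tuple[int, int, str]] = []
    for arm in (structure.acceptor, structure.dhu, structure.anticodon_arm,
                structure.tpsic):
        if not arm.present:
            continue
        for i, j in arm.stem_pairs:
            cls = pair_class(seq[i - 1], seq[j - 1])
            counts[cls] += 1
            if cls == "mismatch":
                mismatches.append((i, j, seq[i - 1] + seq[j - 1]))
    return counts, mismatches


def dot_bracket(structure: CloverleafStructure, length: int) -> str:
    """Dot-bracket string of all stem pairs (1-based structure positions)."""
    chars = ["."] * length
    for arm in (structure.acceptor, structure.dhu, structure.anticodon_arm,
                structure.tpsic):
        if not arm.present:
            continue
        for i, j in arm.stem_pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
    return "".join(chars)


@dataclass(frozen=True)
class FoldReport:
    structures: tuple[tuple[str, CloverleafStructure], ...]
    missing_arm_counts: dict[str, int]
    missing_by_gene: dict[str, tuple[str, ...]]


def fold_all(
    genome: GenomeRecord,
    table: AnnotationTable,
    params: FoldParams = FoldParams(),
) -> FoldReport:
    """Fold every annotated tRNA (strand-aware) and summarise missing arms.

    Expected anticodons come from the annotation's anticodon column when
    present.
    """
    trnas = table.by_class(GeneClass.TRNA)
    if not trnas:
        raise ValueError("annotation contains no tRNA features")
    structures = []
    missing_counts = {"acceptor": 0, "dhu": 0, "anticodon": 0, "tpsic": 0}
    missing_by_gene: dict[str, tuple[str, ...]] = {}
    for f in trnas:
        seq = extract_feature_sequence(genome, f)
        s = fold_cloverleaf(seq, expected_anticodon=f.anticodon, params=params)
        structures.append((f.name, s))
        missing = tuple(arm for arm, ok in s.arms_present.items() if not ok)
        if missing:
            missing_by_gene[f.name] = missing
        for arm in missing:
            missing_counts[arm] += 1
    return FoldReport(
        structures=tuple(structures),
        missing_arm_counts=missing_counts,
        missing_by_gene=missing_by_gene,
    )


def write_structure_report(report: FoldReport, genome: GenomeRecord,
                           table: AnnotationTable, path: str | Path) -> None:
    """Plain-text report: per tRNA a dot-bracket line plus arm/pair summary."""
    with open(path, "w") as fh:
        for name, s in report.structures:
            f = table.feature(name)
            seq = extract_feature_sequence(genome, f)
            fh.write(f">{name} anticodon={s.anticodon or '?'} score={s.score}\n")
            fh.write(seq + "\n")
            fh.write(dot_bracket(s, len(seq)) + "\n")
            present = ",".join(a for a, ok in s.arms_present.items() if ok) or "none"
            pc = s.pairs_classified
            fh.write(
                f"arms={present} wc={pc['watson_crick']} gu={pc['gu_wobble']} "
                f"mismatch={pc['mismatch']}\n"
            )
        fh.write("# missing-arm summary: ")
        fh.write(
            " ".join(f"{arm}={n}" for arm, n in report.missing_arm_counts.items())
            + "\n"
        )
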