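"""Seeded synthetic-mitogenome generator with an exact ground-truth manifest.

Generates a circular insect-style mitogenome — 13 protein-coding genes,
22 tRNAs, 2 rRNAs and one A+T-rich control region in the ancestral insect
gene order — together with a manifest recording exactly what was planted:
coordinates and signed gaps, per-class base counts, realized codon counts,
control-region repeat features, junction motifs and per-tRNA arm
boundaries.  The annotation skeleton is laid out first and the sequence is
built to match it, so the manifest is exact rather than estimated.

Deterministic: the same config and seed produce byte-identical output.

Default study conditions emulate a published walking-stick-insect
mitogenome: ~16 kb total, an A+T-rich region of 1,465 bp at ~87% A+T with
a 19 bp poly-T stretch, a (TA)10 microsatellite, a terminal poly-A element
and two >30 bp segments each planted twice; an ATGATAA motif shared across
the atp8/atp6 overlap and a TTAACTA motif in the trnS2/nad1 spacer; and
trnH/trnM/trnF built without a T-arm.  Guard bases (C/G) flank every
control-region plant so each planted feature is maximal by construction.
Codon weights default to the published codon-usage counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation_io import (
    MINUS,
    PLUS,
    AnnotationTable,
    FeatureAnnotation,
    GeneClass,
    GenomeRecord,
    reverse_complement,
)
from .codon_usage import ALL_CODONS, as_dna
from .reference_tables import reference_codon_counts

__all__ = [
    "GeneSpec",
    "ControlRegionPlan",
    "TrnaArmPlan",
    "SimulationConfig",
    "TruthManifest",
    "generate",
    "write_outputs",
    "ANCESTRAL_INSECT_ORDER",
]


# ---------------------------------------------------------------------------
# Default study conditions


@dataclass(frozen=True)
class GeneSpec:
    name: str
    gene_class: GeneClass
    strand: str
    length: Optional[int] = None  # None: derived (tRNAs from arm plan)
    start_codon: str = "ATG"
    stop: str = "TAA"  # 'TAA' | 'TAG' | 'T' | 'TA' (partial stops)
    anticodon: Optional[str] = None


def _pcg(name, strand, length, start="ATG", stop="TAA"):
    return GeneSpec(name, GeneClass.PCG, strand, length, start, stop)


def _trna(name, strand, anticodon):
    return GeneSpec(name, GeneClass.TRNA, strand, None, anticodon=anticodon)


def _rrna(name, strand, length):
    return GeneSpec(name, GeneClass.RRNA, strand, length)


#: Ancestral insect mitogenome gene order with default strands, lengths near
#: the published ones (PCG lengths adjusted to frame: complete-TAA genes are
#: multiples of 3, partial-T genes leave a 1-nt remainder).
ANCESTRAL_INSECT_ORDER: tuple[GeneSpec, ...] = (
    _trna("trnI", PLUS, "GAT"),
    _trna("trnQ", MINUS, "TTG"),
    _trna("trnM", PLUS, "CAT"),
    _pcg("nad2", PLUS, 1002, "ATC"),
    _trna("trnW", PLUS, "TCA"),
    _trna("trnC", MINUS, "GCA"),
    _trna("trnY", MINUS, "GTA"),
    _pcg("cox1", PLUS, 1536, "ATG"),
    _trna("trnL2", PLUS, "TAA"),
    _pcg("cox2", PLUS, 672, "ATA"),
    _trna("trnK", PLUS, "CTT"),
    _trna("trnD", PLUS, "GTC"),
    _pcg("atp8", PLUS, 159, "ATC"),
    _pcg("atp6", PLUS, 678, "ATG"),
    _pcg("cox3", PLUS, 789, "ATG"),
    _trna("trnG", PLUS, "TCC"),
    _pcg("nad3", PLUS, 352, "ATT", "T"),
    _trna("trnA", PLUS, "TGC"),
    _trna("trnR", PLUS, "TCG"),
    _trna("trnN", PLUS, "GTT"),
    _trna("trnS1", PLUS, "GCT"),
    _trna("trnE", PLUS, "TTC"),
    _trna("trnF", MINUS, "GAA"),
    _pcg("nad5", MINUS, 1723, "ATA", "T"),
    _trna("trnH", MINUS, "GTG"),
    _pcg("nad4", MINUS, 1333, "TTA", "T"),
    _pcg("nad4L", MINUS, 292, "TTA", "T"),
    _trna("trnT", PLUS, "TGT"),
    _trna("trnP", MINUS, "TGG"),
    _pcg("nad6", PLUS, 480, "ATA"),
    _pcg("cob", PLUS, 1132, "ATG", "T"),
    _trna("trnS2", PLUS, "TGA"),
    _pcg("nad1", MINUS, 964, "AAC", "T"),
    _trna("trnL1", MINUS, "TAG"),
    _rrna("rrnL", MINUS, 1258),
    _trna("trnV", MINUS, "TAC"),
    _rrna("rrnS", MINUS, 768),
    GeneSpec("AT_rich", GeneClass.CONTROL_REGION, PLUS, 1465),
)

#: Published >30 bp control-region repeat segments (planted twice each).
_REPEAT_SEGMENTS = (
    "AAAAATTATATTTAATAAATTAATATTTATAAA",
    "TAATTCAATAATAATAATTAATAAATTAATAAT",
)


@dataclass(frozen=True)
class ControlRegionPlan:
    length: int = 1465
    target_at: float = 0.8706
    poly_t: int = 19
    ta_copies: int = 10
    poly_a: int = 12  # terminal poly-A element
    repeats: tuple[str, ...] = _REPEAT_SEGMENTS


@dataclass(frozen=True)
class TrnaArmPlan:
    """Canonical cloverleaf layout used to build each synthetic tRNA."""

    acceptor: int = 7
    spacer1: int = 2
    dhu_stem: int = 4
    dhu_loop: int = 8
    spacer2: int = 1
    ac_stem: int = 5
    ac_loop: int = 7  # anticodon occupies loop positions 3-5
    var_loop: int = 4
    t_stem: int = 5
    t_loop: int = 7
    discriminator: int = 1
    deleted: Optional[str] = None  # None | 'tpsic' | 'dhu'


def _default_gaps() -> dict[tuple[str, str], int]:
    # junction plants (atp8/atp6 overlap, trnS2/nad1 spacer) are added on top
    return {
        ("trnM", "nad2"): 3,
        ("trnY", "cox1"): 2,
        ("cox2", "trnK"): 9,
        ("trnK", "trnD"): 1,
        ("cox3", "trnG"): 4,
        ("nad3", "trnA"): 6,
        ("trnE", "trnF"): 3,
        ("nad5", "trnH"): 2,
        ("nad4L", "trnT"): 2,
        ("trnT", "trnP"): 1,
        ("nad6", "cob"): 5,
        ("nad1", "trnL1"): 4,
        ("rrnL", "trnV"): 2,
    }


def _default_junction_plants() -> dict[tuple[str, str], tuple[str, str]]:
    return {
        ("atp8", "atp6"): ("ATGATAA", "overlap"),
        ("trnS2", "nad1"): ("TTAACTA", "spacer"),
    }


def _default_trna_plans() -> dict[str, TrnaArmPlan]:
    plans = {}
    for spec in ANCESTRAL_INSECT_ORDER:
        if spec.gene_class == GeneClass.TRNA:
            deleted = "tpsic" if spec.name in ("trnH", "trnM", "trnF") else None
            plans[spec.name] = TrnaArmPlan(deleted=deleted)
    return plans


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 1
    gene_order: tuple[GeneSpec, ...] = ANCESTRAL_INSECT_ORDER
    gaps: dict[tuple[str, str], int] = field(default_factory=_default_gaps)
    junction_plants: dict[tuple[str, str], tuple[str, str]] = field(
        default_factory=_default_junction_plants
    )
    control_region: ControlRegionPlan = field(default_factory=ControlRegionPlan)
    trna_plans: dict[str, TrnaArmPlan] = field(default_factory=_default_trna_plans)
    codon_weights: Optional[dict[str, float]] = None  # default: published counts
    rrna_target_at: float = 0.8166
    spacer_at: float = 0.85
    trna_loop_at: float = 0.85
    # A, T, G, C draw weights for stem 5' bases (3' side is the complement)
    trna_stem_weights: tuple[float, float, float, float] = (0.35, 0.35, 0.15, 0.15)

    def validate(self) -> None:
        names = [g.name for g in self.gene_order]
        if len(set(names)) != len(names):
            raise ValueError("gene order contains duplicate names")
        lengths = {g.name: g.length for g in self.gene_order}
        for (a, b), gap in self.effective_gaps().items():
            if a not in lengths or b not in lengths:
                raise ValueError(f"gap references unknown adjacency {(a, b)}")
            if gap < 0:
                la, lb = lengths[a], lengths[b]
                for ln, nm in ((la, a), (lb, b)):
                    if ln is not None and -gap > ln:
                        raise ValueError(
                            f"overlap {gap} at {(a, b)} larger than gene {nm}"
                        )
        for g in self.gene_order:
            if g.length is not None and g.length < 1:
                raise ValueError(f"gene {g.name} has non-positive length")
            if g.gene_class == GeneClass.PCG:
                rem = g.length % 3
                need = {"TAA": 0, "TAG": 0, "T": 1, "TA": 2}[g.stop]
                if rem != need:
                    raise ValueError(
                        f"PCG {g.name}: length {g.length} incompatible with "
                        f"stop {g.stop!r}"
                    )
        if self.codon_weights is not None:
            vals = list(self.codon_weights.values())
            if any(v < 0 for v in vals) or sum(vals) <= 0:
                raise ValueError("codon weights must be non-negative with positive sum")

    def effective_gaps(self) -> dict[tuple[str, str], int]:
        gaps = dict(self.gaps)
        for pair, (motif, mode) in self.junction_plants.items():
            gaps[pair] = -len(motif) if mode == "overlap" else len(motif)
        return gaps


# ---------------------------------------------------------------------------
# Sequence builders

_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}
_BASES = "ATGC"


def _draw_bases(rng: np.random.Generator, n: int, weights) -> str:
    return "".join(rng.choice(list(_BASES), size=n, p=np.asarray(weights) / sum(weights)))


def _exact_at_filler(rng: np.random.Generator, n: int, target_at: float) -> str:
    """Shuffled multiset with largest-remainder base counts hitting target A+T."""
    at = target_at
    props = {"A": at / 2, "T": at / 2, "G": (1 - at) / 2, "C": (1 - at) / 2}
    floors = {b: int(n * p) for b, p in props.items()}
    rem = n - sum(floors.values())
    order = sorted(props, key=lambda b: n * props[b] - floors[b], reverse=True)
    for b in order[:rem]:
        floors[b] += 1
    pool = [b for b, k in floors.items() for _ in range(k)]
    rng.shuffle(pool)
    return "".join(pool)


def _has_bad_filler(seq: str) -> bool:
    """Reject filler with homopolymers >= 8 or dinucleotide tandems >= 4 copies."""
    run = 1
    for i in range(1, len(seq)):
        run = run + 1 if seq[i] == seq[i - 1] else 1
        if run >= 8:
            return True
    count = 1
    for i in range(2, len(seq)):
        if seq[i] == seq[i - 2] and seq[i] != seq[i - 1]:
            count += 1
            if count >= 7:  # 7 extra period-2 positions ~ 4+ copies
                return True
        else:
            count = 1
    return False


def _clean_filler(rng: np.random.Generator, n: int, target_at: float) -> str:
    for _ in range(200):
        s = _exact_at_filler(rng, n, target_at)
        if not _has_bad_filler(s):
            return s
    raise RuntimeError("could not draw control-region filler without spurious repeats")


def _build_pcg(rng: np.random.Generator, spec: GeneSpec,
               codons: list[str], weights: np.ndarray) -> str:
    """Reading-strand CDS: start codon + weighted body codons + stop tail."""
    tail = spec.stop if spec.stop in ("T", "TA") else spec.stop
    n_body = (spec.length - 3 - len(tail)) // 3
    if spec.stop in ("TAA", "TAG"):
        n_body = (spec.length - 6) // 3
        body = "".join(rng.choice(codons, size=n_body, p=weights))
        return spec.start_codon + body + spec.stop
    n_body = (spec.length - 3 - len(tail)) // 3
    body = "".join(rng.choice(codons, size=n_body, p=weights))
    return spec.start_codon + body + tail


def _build_trna(rng: np.random.Generator, plan: TrnaArmPlan, anticodon: str,
                loop_at: float, stem_w) -> tuple[str, dict]:
    """(sequence, truth) for one tRNA; truth holds 1-based arm stem pairs.

    Loop, spacer and variable-loop bases are drawn from {A, C} only: A and C
    pair with neither each other nor themselves (no Watson-Crick, no G·U),
    so unpaired regions cannot form accidental stems and the planted arms
    are the unique best-scoring assembly up to rare stem self-similarity.
    ``loop_at`` is the A fraction (hence the A+T contribution) of these
    unpaired regions.
    """

    def loop_bases(k: int) -> str:
        return "".join(rng.choice(["A", "C"], size=k, p=[loop_at, 1 - loop_at]))

    def stem_bases(k: int) -> str:
        # stems must be aperiodic at shifts 1 and 2: a stem like TTTT or TATA
        # pairs its own complement shifted by one or two positions, making a
        # displaced stem score identically and the planted arm ambiguous;
        # draw each base excluding the previous two, weights renormalised
        out: list[str] = []
        for _ in range(k):
            allowed = [b for b in _BASES if b not in out[-2:]]
            w = np.array([stem_w[_BASES.index(b)] for b in allowed], dtype=float)
            out.append(str(rng.choice(allowed, p=w / w.sum())))
        return "".join(out)

    parts: list[str] = []
    pos = 0
    truth: dict = {}

    def add(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        span = (pos + 1, pos + len(s))  # 1-based inclusive
        pos += len(s)
        return span

    acc5 = stem_bases(plan.acceptor)
    acc5_span = add(acc5)
    add(loop_bases(plan.spacer1))

    arms = []
    if plan.deleted != "dhu":
        d5 = stem_bases(plan.dhu_stem)
        d5_span = add(d5)
        d_loop_span = add(loop_bases(plan.dhu_loop))
        d3_span = add("".join(_COMPL[b] for b in reversed(d5)))
        truth["dhu"] = {
            "stem_pairs": [
                (d5_span[0] + k, d3_span[1] - k) for k in range(plan.dhu_stem)
            ],
            "loop_span": d_loop_span,
            "present": True,
        }
        add(loop_bases(plan.spacer2))
    else:
        add(loop_bases(plan.spacer2 + 3))
        truth["dhu"] = {"stem_pairs": [], "loop_span": None, "present": False}

    a5 = stem_bases(plan.ac_stem)
    a5_span = add(a5)
    loop = loop_bases(2) + anticodon + loop_bases(plan.ac_loop - 5)
    a_loop_span = add(loop)
    a3_span = add("".join(_COMPL[b] for b in reversed(a5)))
    truth["anticodon"] = {
        "stem_pairs": [(a5_span[0] + k, a3_span[1] - k) for k in range(plan.ac_stem)],
        "loop_span": a_loop_span,
        "present": True,
        "anticodon": anticodon,
    }

    if plan.deleted != "tpsic":
        var = loop_bases(plan.var_loop)
        # guard: the last variable-loop base must not pair with the first
        # 3'-acceptor base, or a left-shifted T-arm would tie the planted one
        acc3_first = _COMPL[acc5[-1]]
        if acc3_first in ("T", "G"):  # T pairs A, G pairs C (and wobbles T)
            var = var[:-1] + ("C" if acc3_first == "T" else "A")
        add(var)
        t5 = stem_bases(plan.t_stem)
        t5_span = add(t5)
        t_loop_span = add(loop_bases(plan.t_loop))
        t3_span = add("".join(_COMPL[b] for b in reversed(t5)))
        truth["tpsic"] = {
            "stem_pairs": [
                (t5_span[0] + k, t3_span[1] - k) for k in range(plan.t_stem)
            ],
            "loop_span": t_loop_span,
            "present": True,
        }
    else:
        add(loop_bases(plan.var_loop + 2))
        truth["tpsic"] = {"stem_pairs": [], "loop_span": None, "present": False}

    acc3_span = add("".join(_COMPL[b] for b in reversed(acc5)))
    add(loop_bases(plan.discriminator))
    truth["acceptor"] = {
        "stem_pairs": [
            (acc5_span[0] + k, acc3_span[1] - k) for k in range(plan.acceptor)
        ],
        "loop_span": None,
        "present": True,
    }
    return "".join(parts), truth


def _identifiable_trna(rng: np.random.Generator, plan: TrnaArmPlan,
                       anticodon: str, loop_at: float, stem_w) -> tuple[str, dict]:
    """Draw a tRNA whose planted arms are the unique best-scoring fold.

    The aperiodic stems and non-pairing {A,C} unpaired regions already make
    accidental alternative stems rare, but spacer bases can still pair with
    stem bases by chance and tie a displaced arm.  The planted structure is
    ground truth, so each draw is verified by the default folding heuristic
    and redrawn on the rare ambiguity.
    """
    from .trna_cloverleaf import fold_cloverleaf

    for _ in range(50):
        seq, truth = _build_trna(rng, plan, anticodon, loop_at, stem_w)
        s = fold_cloverleaf(seq, expected_anticodon=anticodon)
        folded = {
            "acceptor": s.acceptor, "dhu": s.dhu,
            "anticodon": s.anticodon_arm, "tpsic": s.tpsic,
        }
        if all(
            arm.present == truth[k]["present"]
            and [list(p) for p in arm.stem_pairs]
            == [list(p) for p in truth[k]["stem_pairs"]]
            for k, arm in folded.items()
        ):
            return seq, truth
    raise RuntimeError("could not draw an unambiguous tRNA structure")


def _build_control_region(rng: np.random.Generator,
                          plan: ControlRegionPlan) -> tuple[str, list[dict]]:
    """(sequence, planted repeat-feature truth with region-relative starts).

    Every plant is flanked by C/G guard bases so detected features are
    maximal exactly at their planted coordinates; the two occurrences of a
    repeat segment get different guards so pairwise extension stops at the
    planted boundary.
    """
    # order: poly-T, (TA)n, repeat segments (two occurrences each), terminal poly-A
    items: list[tuple[str, str, str, dict]] = []
    items.append(("C", "T" * plan.poly_t, "G",
                  {"kind": "homopolymer", "unit": "T", "copies": plan.poly_t}))
    items.append(("C", "TA" * plan.ta_copies, "G",
                  {"kind": "microsatellite", "unit": "AT", "copies": plan.ta_copies}))
    for idx, seg in enumerate(plan.repeats):
        items.append(("C", seg, "C", {"kind": "direct_repeat", "unit": seg,
                                      "occurrence": 0, "segment": idx}))
        items.append(("G", seg, "G", {"kind": "direct_repeat", "unit": seg,
                                      "occurrence": 1, "segment": idx}))
    terminal = ("C", "A" * plan.poly_a, "",
                {"kind": "homopolymer", "unit": "A", "copies": plan.poly_a})

    fixed = sum(len(g1) + len(s) + len(g2) for g1, s, g2 in
                [(i[0], i[1], i[2]) for i in items + [terminal]])
    n_fill = plan.length - fixed
    if n_fill < len(items) + 1:
        raise ValueError("control region too short for the requested plants")
    # filler chunk lengths: spread evenly, remainder to the first chunk
    n_chunks = len(items) + 1  # before each item and before the terminal poly-A
    base_len = n_fill // n_chunks
    chunk_lens = [base_len] * n_chunks
    chunk_lens[0] += n_fill - base_len * n_chunks

    seq_parts: list[str] = []
    truth: list[dict] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        seq_parts.append(s)
        start = pos + 1
        pos += len(s)
        return start

    pending_repeats: dict[int, dict] = {}
    for chunk_len, (gl, body, gr, meta) in zip(chunk_lens, items):
        emit(_clean_filler(rng, chunk_len, plan.target_at))
        emit(gl)
        start = emit(body)
        emit(gr)
        if meta["kind"] == "direct_repeat":
            seg = meta["segment"]
            if meta["occurrence"] == 0:
                pending_repeats[seg] = {"start": start, "unit": meta["unit"]}
            else:
                first = pending_repeats.pop(seg)
                truth.append(
                    {
                        "kind": "direct_repeat",
                        "start": first["start"],
                        "length": len(meta["unit"]),
                        "unit": meta["unit"],
                        "copies": 2,
                        "mate_start": start,
                    }
                )
        else:
            truth.append(
                {
                    "kind": meta["kind"],
                    "start": start,
                    "length": len(body),
                    "unit": meta["unit"],
                    "copies": meta["copies"],
                    "mate_start": None,
                }
            )
    gl, body, gr, meta = terminal
    emit(_clean_filler(rng, chunk_lens[-1], plan.target_at))
    emit(gl)
    start = emit(body)
    truth.append(
        {"kind": "homopolymer", "start": start, "length": len(body),
         "unit": "A", "copies": meta["copies"], "mate_start": None}
    )
    seq = "".join(seq_parts)
    if len(seq) != plan.length:
        raise AssertionError("control-region assembly length mismatch")
    truth.sort(key=lambda d: d["start"])
    return seq, truth


# ---------------------------------------------------------------------------
# Manifest and generation


@dataclass
class TruthManifest:
    """Exact ground truth of one generated genome (JSON-serialisable)."""

    genome_id: str
    genome_length: int
    seed: int
    features: list[dict]  # name, class, strand, start, end, size
    gaps: dict[str, int]  # "a|b" -> signed bp
    class_base_counts: dict[str, dict[str, int]]
    codon_counts: dict[str, int]  # realized, RNA codons
    control_region_plants: list[dict]
    junction_plants: dict[str, str]  # "a|b" -> motif
    trna_arms: dict[str, dict]

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(asdict(self), indent=indent)

    @staticmethod
    def from_json(text: str) -> "TruthManifest":
        return TruthManifest(**json.loads(text))


def generate(config: SimulationConfig | None = None,
             seed: Optional[int] = None) -> tuple[GenomeRecord, AnnotationTable, TruthManifest]:
    """Generate one synthetic mitogenome (deterministic in config + seed)."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    config.validate()
    rng = np.random.default_rng(config.seed)

    weights_map = config.codon_weights or {
        c: float(n) for c, n in reference_codon_counts().items()
    }
    codons_dna = [as_dna(c) for c in ALL_CODONS]
    w = np.array([weights_map.get(c, weights_map.get(as_dna(c), 0.0))
                  for c in ALL_CODONS], dtype=float)
    w = w / w.sum()

    # 1. build reading-strand sequences and derive lengths
    seqs: dict[str, str] = {}
    trna_truth: dict[str, dict] = {}
    cr_truth: list[dict] = []
    for spec in config.gene_order:
        if spec.gene_class == GeneClass.PCG:
            seqs[spec.name] = _build_pcg(rng, spec, codons_dna, w)
        elif spec.gene_class == GeneClass.TRNA:
            plan = config.trna_plans.get(spec.name, TrnaArmPlan())
            seq, truth = _identifiable_trna(rng, plan, spec.anticodon,
                                            config.trna_loop_at,
                                            config.trna_stem_weights)
            seqs[spec.name] = seq
            trna_truth[spec.name] = truth
        elif spec.gene_class == GeneClass.RRNA:
            seqs[spec.name] = _exact_at_filler(rng, spec.length, config.rrna_target_at)
        else:
            seq, cr_truth = _build_control_region(rng, config.control_region)
            seqs[spec.name] = seq

    # overlap-mode junction motifs: the downstream gene owns the shared bases,
    # so its reading-strand prefix is forced to the motif (its start codon is
    # the motif's first triplet by construction of sensible configs)
    by_name = {spec.name: spec for spec in config.gene_order}
    for (a, b), (motif, mode) in config.junction_plants.items():
        if mode != "overlap":
            continue
        if by_name[a].strand != PLUS or by_name[b].strand != PLUS:
            raise ValueError(
                f"overlap junction plant {(a, b)} requires plus-strand genes"
            )
        seqs[b] = motif + seqs[b][len(motif):]

    # 2. coordinates from lengths + gaps
    gaps = config.effective_gaps()
    order = list(config.gene_order)
    coords: list[tuple[int, int]] = []
    pos = 0  # end of previous feature
    for i, spec in enumerate(order):
        gap = 0
        if i > 0:
            gap = gaps.get((order[i - 1].name, spec.name), 0)
        start = pos + gap + 1
        end = start + len(seqs[spec.name]) - 1
        coords.append((start, end))
        pos = end
    wrap_gap = gaps.get((order[-1].name, order[0].name), 0)
    genome_length = pos + wrap_gap

    # 3. assemble: place genomic-strand sequences in order (downstream gene
    # owns overlapping bases by overwriting), then fill spacers
    arr = [None] * genome_length
    for spec, (start, end) in zip(order, coords):
        s = seqs[spec.name]
        if spec.strand == MINUS:
            s = reverse_complement(s)
        for k, b in enumerate(s):
            arr[start - 1 + k] = b
    # junction spacer motifs
    for (a, b), (motif, mode) in config.junction_plants.items():
        if mode != "spacer":
            continue
        ia = next(i for i, sp in enumerate(order) if sp.name == a)
        a_end = coords[ia][1]
        for k, ch in enumerate(motif):
            arr[a_end + k] = ch
    # remaining spacer filler
    holes = [i for i, b in enumerate(arr) if b is None]
    if holes:
        at = config.spacer_at
        fill = _draw_bases(rng, len(holes), [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
        for i, b in zip(holes, fill):
            arr[i] = b
    genome_seq = "".join(arr)

    genome_id = f"synthetic_mitogenome_seed{config.seed}"
    genome = GenomeRecord(id=genome_id, seq=genome_seq, circular=True)

    features = [
        FeatureAnnotation(
            name=spec.name,
            gene_class=spec.gene_class,
            strand=spec.strand,
            start=start,
            end=end,
            anticodon=spec.anticodon,
            start_codon=spec.start_codon if spec.gene_class == GeneClass.PCG else None,
            stop_codon=spec.stop if spec.gene_class == GeneClass.PCG else None,
        )
        for spec, (start, end) in zip(order, coords)
    ]
    table = AnnotationTable(
        genome_id=genome_id, genome_length=genome_length, features=features
    )

    # 4. manifest from the assembled genome (realized, not intended, values)
    from .codon_usage import count_codons  # local import avoids cycle at module load
    from .annotation_io import extract_feature_sequence

    class_counts: dict[str, dict[str, int]] = {}
    pcg_seqs = []
    for f in features:
        s = extract_feature_sequence(genome, f)
        cls = f.gene_class.value
        bucket = class_counts.setdefault(cls, {b: 0 for b in "ACGTN"})
        for b in "ACGTN":
            bucket[b] += s.count(b)
        if f.gene_class == GeneClass.PCG:
            pcg_seqs.append(s)
    codon_counts = count_codons(pcg_seqs).counts

    manifest = TruthManifest(
        genome_id=genome_id,
        genome_length=genome_length,
        seed=config.seed,
        features=[
            {
                "name": f.name,
                "class": f.gene_class.value,
                "strand": f.strand,
                "start": f.start,
                "end": f.end,
                "size": f.end - f.start + 1,
            }
            for f in features
        ],
        gaps={
            f"{a}|{b}": g
            for (a, b), g in gaps.items()
        },
        class_base_counts=class_counts,
        codon_counts=dict(codon_counts),
        control_region_plants=cr_truth,
        junction_plants={f"{a}|{b}": motif
                         for (a, b), (motif, _) in config.junction_plants.items()},
        trna_arms=trna_truth,
    )
    return genome, table, manifest


def write_outputs(genome: GenomeRecord, table: AnnotationTable,
                  manifest: TruthManifest, outdir: str | Path) -> None:
    """Emit FASTA + GenBank + feature-table TSV + JSON manifest."""
    from .annotation_io import write_fasta, write_feature_table, write_genbank

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([genome], outdir / "genome.fasta")
    write_feature_table(table, outdir / "annotation.tsv")
    write_genbank(genome, table, outdir / "genome.gb")
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
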