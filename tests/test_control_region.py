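"""Control-region repeat detectors vs naive oracles and planted features."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoprofile.control_region import (
    RegionParams,
    homopolymer_runs,
    long_direct_repeats,
    microsatellites,
    region_report,
)

at_rich = st.text(alphabet="AATTG C".replace(" ", ""), min_size=0, max_size=400)


# ---------------------------------------------------------------------------
# naive oracles


def oracle_homopolymers(seq, min_len):
    out = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            out.append((i + 1, j - i, seq[i]))
        i = j
    return out


def oracle_microsatellites(seq, unit_len, min_copies):
    """Maximal period-u runs trimmed to whole copies, by exhaustive scan."""
    n = len(seq)
    out = []
    starts_done = set()
    for i in range(n):
        if i in starts_done:
            continue
        # longest stretch from i where seq[k] == seq[k - unit_len]
        j = i + unit_len
        if j > n or seq[i : i + unit_len] != seq[j - unit_len : j]:
            pass
        j = i + unit_len
        while j < n and seq[j] == seq[j - unit_len]:
            j += 1
        copies = (j - i) // unit_len
        if copies >= min_copies and j - i > unit_len:
            unit = seq[i : i + unit_len]
            if not (unit_len > 1 and len(set(unit)) == 1):
                out.append((i + 1, copies * unit_len, copies))
            for k in range(i + 1, j - unit_len + 1):
                starts_done.add(k)  # sub-runs of the same periodic region
    return out


def oracle_direct_repeats(seq, min_len):
    """All maximal repeated pairs by O(n^2) longest-common-extension."""
    n = len(seq)
    found = set()
    for i in range(n):
        for j in range(i + 1, n):
            if seq[i] != seq[j]:
                continue
            if i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                continue  # not left-maximal
            length = 0
            while j + length < n and seq[i + length] == seq[j + length]:
                length += 1
            if length >= min_len:
                found.add((i + 1, j + 1, length))
    return found


# ---------------------------------------------------------------------------


class TestHomopolymers:
    def test_poly_t_stretch(self):
        seq = "AA" + "T" * 19 + "CC"
        (run,) = homopolymer_runs(seq, min_len=10)
        assert (run.unit, run.length, run.start) == ("T", 19, 3)

    def test_no_runs(self):
        assert homopolymer_runs("ACGT", min_len=2) == []

    def test_maximality_no_subruns(self):
        runs = homopolymer_runs("T" * 5, min_len=5)
        assert len(runs) == 1 and runs[0].length == 5

    @given(at_rich, st.integers(2, 6))
    def test_matches_oracle(self, seq, min_len):
        got = [(r.start, r.length, r.unit) for r in homopolymer_runs(seq, min_len)]
        assert got == oracle_homopolymers(seq, min_len)


class TestMicrosatellites:
    def test_ta_ten(self):
        seq = "GGC" + "TA" * 10 + "CGG"
        (m,) = microsatellites(seq, unit_len=2, min_copies=5)
        assert (m.unit, m.copies, m.length, m.start) == ("AT", 10, 20, 4)

    def test_below_copy_threshold(self):
        assert microsatellites("TATATA", unit_len=2, min_copies=4) == []

    def test_homopolymer_unit_excluded(self):
        assert microsatellites("TTTTTTTTTT", unit_len=2, min_copies=2) == []

    @given(at_rich, st.integers(2, 4))
    def test_matches_exhaustive_oracle(self, seq, min_copies):
        got = [(m.start, m.length, m.copies)
               for m in microsatellites(seq, 2, min_copies)]
        assert got == oracle_microsatellites(seq, 2, min_copies)

    def test_reported_array_maximality(self):
        seq = "CC" + "TA" * 7 + "GG"
        (m,) = microsatellites(seq, 2, 5)
        sub = seq[m.start - 1 : m.start - 1 + m.length]
        assert sub == "TA" * 7
        # extending one base in either direction breaks the periodicity
        assert seq[m.start - 2] != seq[m.start]  # left
        assert seq[m.start - 1 + m.length] != seq[m.start - 1 + m.length - 2]


class TestDirectRepeats:
    def test_planted_segment_twice(self):
        seg = "AAAAATTATATTTAATAAATTAATATTTATAAA"  # 33 bp
        rng = random.Random(7)
        filler = "".join(rng.choice("ACGT") for _ in range(200))
        seq = filler[:90] + "C" + seg + "C" + filler[90:150] + "G" + seg + "G" + filler[150:]
        (rep,) = long_direct_repeats(seq, min_len=30)
        assert rep.length == 33
        assert rep.unit == seg
        assert rep.copies == 2

    def test_random_four_letter_string_has_no_30bp_repeat(self):
        rng = random.Random(123)
        seq = "".join(rng.choice("ACGT") for _ in range(100))
        assert long_direct_repeats(seq, min_len=30) == []
        assert oracle_direct_repeats(seq, 30) == set()

    def test_back_to_back_duplication(self):
        x = "ACGTACGTTT"
        (rep,) = long_direct_repeats("G" + x + x + "C", min_len=len(x))
        assert (rep.start, rep.mate_start, rep.length) == (2, 2 + len(x), len(x))

    @given(at_rich, st.integers(8, 12))
    @settings(max_examples=30)
    def test_matches_quadratic_oracle(self, seq, min_len):
        got = {(r.start, r.mate_start, r.length)
               for r in long_direct_repeats(seq, min_len)}
        assert got == oracle_direct_repeats(seq, min_len)

    def test_oracle_agreement_on_synthetic_region_2kb(self, default_sim):
        from mitoprofile.annotation_io import extract_feature_sequence

        genome, table, _ = default_sim
        region = table.feature("AT_rich")
        seq = extract_feature_sequence(genome, region)[:2000]
        got = {(r.start, r.mate_start, r.length)
               for r in long_direct_repeats(seq, 30)}
        assert got == oracle_direct_repeats(seq, 30)

    def test_reextraction_matches_unit(self, default_sim):
        genome, table, _ = default_sim
        rep = region_report(genome, table)
        for f in rep.features:
            sub = None
            from mitoprofile.annotation_io import extract_feature_sequence

            region_seq = extract_feature_sequence(genome, table.feature("AT_rich"))
            sub = region_seq[f.start - 1 : f.start - 1 + f.length]
            if f.kind == "homopolymer":
                assert sub == f.unit * f.copies
            elif f.kind == "microsatellite":
                assert len(sub) == f.copies * len(f.unit)
                assert set(sub[::2]) <= set(f.unit) and set(sub[1::2]) <= set(f.unit)
            else:
                assert sub == f.unit
                mate = region_seq[f.mate_start - 1 : f.mate_start - 1 + f.length]
                assert mate == f.unit


class TestRegionReport:
    def test_all_planted_features_recovered_exactly(self, default_sim):
        genome, table, manifest = default_sim
        rep = region_report(genome, table)
        got = [(f.kind, f.start, f.length, f.unit, f.copies, f.mate_start)
               for f in rep.features]
        want = [(p["kind"], p["start"], p["length"], p["unit"], p["copies"],
                 p["mate_start"]) for p in manifest.control_region_plants]
        assert got == want

    def test_featureless_region_reports_nothing(self):
        from mitoprofile.annotation_io import (
            AnnotationTable,
            FeatureAnnotation,
            GeneClass,
            GenomeRecord,
        )

        # a periodic ACGT tiling carries no homopolymers or dinucleotide
        # microsatellites; a seeded random region additionally carries no
        # >=30 bp direct repeat (verified by the oracle above)
        g1 = GenomeRecord(id="g1", seq="ACGT" * 100)
        t1 = AnnotationTable(
            "g1", 400,
            [FeatureAnnotation("CR", GeneClass.CONTROL_REGION, "+", 1, 400)],
        )
        rep1 = region_report(g1, t1)
        assert not any(f.kind in ("homopolymer", "microsatellite")
                       for f in rep1.features)

        rng = random.Random(99)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        assert oracle_direct_repeats(seq, 30) == set()
        g2 = GenomeRecord(id="g2", seq=seq)
        t2 = AnnotationTable(
            "g2", 400,
            [FeatureAnnotation("CR", GeneClass.CONTROL_REGION, "+", 1, 400)],
        )
        assert region_report(g2, t2).features == ()

    def test_detection_independent_of_genomic_offset(self):
        from mitoprofile.annotation_io import (
            AnnotationTable,
            FeatureAnnotation,
            GeneClass,
            GenomeRecord,
        )

        core = "GG" + "T" * 12 + "CC" + "TA" * 6 + "GG"
        pad = "ACGT" * 25
        for offset in (0, 40):
            seq = pad[:offset] + core + pad[offset:]
            g = GenomeRecord(id="g", seq=seq)
            start = offset + 1
            t = AnnotationTable(
                "g", len(seq),
                [FeatureAnnotation("CR", GeneClass.CONTROL_REGION, "+",
                                   start, offset + len(core))],
            )
            rep = region_report(g, t)
            rel = [(f.kind, f.start, f.length) for f in rep.features]
            assert rel == [("homopolymer", 3, 12), ("microsatellite", 17, 12)]
            for f in rep.features:
                assert f.abs_start == offset + f.start

    def test_missing_control_region_is_error(self, default_sim):
        from mitoprofile.annotation_io import AnnotationTable, GeneClass

        genome, table, _ = default_sim
        t2 = AnnotationTable(
            table.genome_id, table.genome_length,
            [f for f in table.features
             if f.gene_class != GeneClass.CONTROL_REGION],
        )
        with pytest.raises(ValueError, match="control"):
            region_report(genome, t2)
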