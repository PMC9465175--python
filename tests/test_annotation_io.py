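"""Genome/annotation I/O: FASTA, feature-table dialect, GenBank, extraction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitoprofile.annotation_io import (
    AnnotationTable,
    FeatureAnnotation,
    GeneClass,
    GenomeRecord,
    extract_feature_sequence,
    extract_span,
    read_fasta,
    read_feature_table,
    read_genbank,
    reverse_complement,
    write_feature_table,
    write_genbank,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def make_feature(name="x", strand="+", start=1, end=1, gene_class=GeneClass.TRNA):
    return FeatureAnnotation(name=name, gene_class=gene_class, strand=strand,
                             start=start, end=end)


class TestReadFasta:
    def test_reads_records_in_order_with_normalisation(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGT\n>y\nacgu\n")
        recs = read_fasta(p)
        assert [(r.id, r.seq, r.length) for r in recs] == [
            ("x", "ACGT", 4), ("y", "ACGT", 4),
        ]

    def test_full_length_mitogenome_record(self, tmp_path):
        seq = "ACGT" * 4015  # 16,060 bp, a typical phasmid mitogenome length
        p = tmp_path / "g.fasta"
        p.write_text(">mt\n" + seq + "\n")
        assert read_fasta(p)[0].length == 16060

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_invalid_character_names_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nACXT\n")
        with pytest.raises(ValueError, match="position 3"):
            read_fasta(p)


class TestFeatureTable:
    HEADER = ("Gene\tDirection\tLocation\tSize (bp)\tAnticodon\tStart codon\t"
              "Stop codon\tIntergenic Nucleotides *\n")

    def _read(self, tmp_path, rows, genome_length=20000):
        p = tmp_path / "t.tsv"
        p.write_text(self.HEADER + "".join(r + "\n" for r in rows))
        return read_feature_table(p, genome_length=genome_length)

    def test_en_dash_location_and_markup_stripped(self, tmp_path):
        t = self._read(tmp_path, ["*cox1*\t+\t1392–2925\t1534\t\tATG\t\t−1"])
        f = t.feature("cox1")
        assert (f.start, f.end, f.gene_class) == (1392, 2925, GeneClass.PCG)
        assert t.ign == [-1]  # unicode minus accepted

    def test_thousands_separator(self, tmp_path):
        t = self._read(tmp_path, ["A+T-rich region\t\t14,596–16060\t1465\t\t\t\t"])
        f = t.features[0]
        assert (f.start, f.end) == (14596, 16060)
        assert f.gene_class == GeneClass.CONTROL_REGION

    def test_single_base_feature(self, tmp_path):
        t = self._read(tmp_path, ["trnX\t+\t5-5\t1\t\t\t\t0"])
        assert (t.features[0].start, t.features[0].end) == (5, 5)

    def test_unparseable_location_names_row(self, tmp_path):
        with pytest.raises(ValueError, match="trnBad"):
            self._read(tmp_path, ["trnBad\t+\tnowhere\t\t\t\t\t"])

    def test_duplicate_gene_name_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            self._read(tmp_path, ["trnA\t+\t1-5\t\t\t\t\t", "trnA\t+\t6-9\t\t\t\t\t"])

    def test_write_read_round_trip_is_identity(self, tmp_path):
        table = AnnotationTable(
            genome_id="g", genome_length=1000,
            features=[
                FeatureAnnotation("trnA", GeneClass.TRNA, "+", 1, 70, anticodon="TGC"),
                FeatureAnnotation("nad2", GeneClass.PCG, "-", 71, 940,
                                  start_codon="ATT", stop_codon="T"),
                FeatureAnnotation("CR", GeneClass.CONTROL_REGION, "+", 941, 1000),
            ],
            ign=[0, -2, None],
            printed_sizes=[70, 870, 60],
        )
        p = tmp_path / "rt.tsv"
        write_feature_table(table, p)
        back = read_feature_table(p, genome_length=1000, genome_id="g")
        assert back.features == table.features
        assert back.ign == table.ign
        assert back.printed_sizes == table.printed_sizes


class TestGenBank:
    def test_minus_strand_and_wrap_round_trip(self, tmp_path):
        genome = GenomeRecord(id="g1", seq="ACGTACGTAA" * 30, circular=True)
        table = AnnotationTable(
            genome_id="g1", genome_length=300,
            features=[
                FeatureAnnotation("trnZ", GeneClass.TRNA, "-", 1, 67),
                FeatureAnnotation("wrapped", GeneClass.PCG, "+", 290, 20),
                FeatureAnnotation("rrnX", GeneClass.RRNA, "+", 100, 250),
            ],
        )
        p = tmp_path / "g.gb"
        write_genbank(genome, table, p)
        g2, t2 = read_genbank(p)
        assert g2.seq == genome.seq
        got = {(f.name, f.strand, f.start, f.end, f.gene_class) for f in t2.features}
        want = {(f.name, f.strand, f.start, f.end, f.gene_class)
                for f in table.features}
        assert got == want

    def test_synthetic_genome_round_trips(self, default_sim, tmp_path):
        genome, table, _ = default_sim
        p = tmp_path / "sim.gb"
        write_genbank(genome, table, p)
        g2, t2 = read_genbank(p)
        assert g2.seq == genome.seq
        assert [(f.name, f.strand, f.start, f.end) for f in t2.features] == [
            (f.name, f.strand, f.start, f.end) for f in table.features
        ]

    def test_missing_origin_is_error(self, tmp_path):
        p = tmp_path / "no_origin.gb"
        p.write_text(
            "LOCUS       g1 10 bp DNA circular 01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n//\n"
        )
        with pytest.raises(ValueError):
            read_genbank(p)


class TestExtraction:
    genome = GenomeRecord(id="g", seq="AACGTT", circular=True)

    @pytest.mark.parametrize(
        "strand,start,end,expected",
        [
            ("+", 2, 4, "ACG"),
            ("-", 2, 4, "CGT"),  # reverse complement of ACG
            ("+", 5, 2, "TTAA"),  # wraps the origin
            ("-", 5, 2, "TTAA"),  # revcomp of TTAA is TTAA
        ],
    )
    def test_extraction(self, strand, start, end, expected):
        f = make_feature(strand=strand, start=start, end=end)
        assert extract_feature_sequence(self.genome, f) == expected

    def test_wrap_matches_rotation_oracle(self):
        # brute force: rotate so start becomes position 1, then take a prefix
        seq = self.genome.seq
        for start in range(1, 7):
            for end in range(1, 7):
                if start <= end:
                    continue
                rotated = seq[start - 1 :] + seq[: start - 1]
                length = (6 - start + 1) + end
                assert extract_span(self.genome, start, end) == rotated[:length]

    def test_wrap_on_linear_genome_is_error(self):
        g = GenomeRecord(id="lin", seq="AACGTT", circular=False)
        with pytest.raises(ValueError, match="wrap"):
            extract_span(g, 5, 2)

    @given(dna)
    def test_minus_strand_is_reverse_complement_of_plus(self, seq):
        g = GenomeRecord(id="g", seq=seq, circular=True)
        f_plus = make_feature(strand="+", start=1, end=len(seq))
        f_minus = make_feature(strand="-", start=1, end=len(seq))
        assert extract_feature_sequence(g, f_minus) == reverse_complement(
            extract_feature_sequence(g, f_plus)
        )

    @given(st.data())
    def test_non_wrapped_length_contract(self, data):
        seq = data.draw(dna)
        start = data.draw(st.integers(1, len(seq)))
        end = data.draw(st.integers(start, len(seq)))
        g = GenomeRecord(id="g", seq=seq, circular=True)
        f = make_feature(start=start, end=end)
        assert len(extract_feature_sequence(g, f)) == end - start + 1
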