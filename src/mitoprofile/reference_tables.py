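"""Published reference tables for the Ramulus irregulatiter dentatus mitogenome.

Two small fixtures transcribed from the published annotation of this
16,060 bp walking-stick-insect mitogenome: the gene-arrangement table
(coordinates, printed sizes, anticodons, start/stop codons and the printed
intergenic-nucleotide column, kept verbatim even where they disagree with
the coordinates) and the codon-usage table (printed counts and RSCU values
for all 64 codons).

The printed direction column of the source table marks the majority (H)
strand with a dash and the minority (L) strand with a plus sign; here the
strands are normalised to explicit +/-.
"""

from __future__ import annotations

from functools import lru_cache

from .annotation_io import AnnotationTable, read_feature_table

__all__ = [
    "REFERENCE_GENOME_LENGTH",
    "reference_annotation_table",
    "reference_codon_usage",
    "reference_codon_counts",
]

REFERENCE_GENOME_LENGTH = 16060

# Gene / Direction / Location / Size (bp) / Anticodon / Start codon /
# Stop codon / Intergenic Nucleotides — verbatim printed values; locations
# keep the printed en-dashes and thousands separators.
_ANNOTATION_TSV = """\
Gene	Direction	Location	Size (bp)	Anticodon	Start codon	Stop codon	Intergenic Nucleotides *
trnI	+	1–67	68	GAT		TA	−4
trnQ	-	65–133	79	TTG	TTA	TA	−2
trnM	+	133–199	67	CAT	AGA		5
nad2	+	203–1208	1006		ATC	TTA	−11
trnW	+	1209–1273	65	TCA		TA	−9
trnC	-	1266–1327	62	GCA			−1
trnY	-	1328–1390	83	GTA		TA	2
cox1	+	1392–2925	1534		ATG		−1
trnL2(UUR)	+	2926–2989	64	TAA			2
cox2	+	2990–3659	670		ATA		9
trnK	+	3660–3729	67	CTT			−2
trnD	+	3729–3795	76	GTC			−2
atp8	+	3796–3954	159		ATC	TAA	−5
atp6	+	3946–4625	678		ATG		8
cox3	+	4625–5413	789		ATG	TAA	4
trnG	+	5413–5477	65	TCC	ATT		2
nad3	+	5478–5829	352		ATT	T	6
trnA	+	5830–5894	65	TGC			−1
trnR	+	5895–5963	69	TCG			−1
trnN	+	5964–6027	64	GTT			−1
trnS1(AGN)	+	6027–6096	70	GCT			−1
trnE	+	6096–6159	64	TTC	ATT		0
trnF	-	6161–6223	63	GAA			3
nad5	-	6224–7946	1723		ATA	T	2
trnH	-	7947–8009	63	GTG		TT	−2
nad4	-	8009–9340	1332		TTA	T	−7
nad4L	-	9334–9624	291		TTA	T	2
trnT	+	9627–9688	62	TGT			−1
trnP	-	9689–9753	65	TGG		T	0
nad6	+	9755–10,234	480		ATA	TAA	5
cob	+	10,234–11,365	1132		ATG	T	2
trnS2(UCN)	+	11,366–11,433	68	TGA		TTA	−1
nad1	-	11,434–12,396	964		AAC	T	4
trnL1(CUN)	-	12,401–12,467	67	GTA			−31
rrnL	-	12,468–13,758	1258			T	2
trnV	-	13,759–13,826	68	TAC			0
rrnS	-	13,827–14,595	768				0
A+T-rich region		14,596–16060	1465				—
"""

# Codon(aa) / No. / RSCU, four column groups, verbatim printed values.
_CODON_TSV = """\
UUU(F)	117	1.44	UCU(S)	30	1.10	UAU(Y)	193	1.37	UGU(C)	22	1.29
UUC(F)	45	0.56	UCC(S)	18	0.66	UAC(Y)	88	0.63	UGC(C)	12	0.71
UUA(L)	199	2.80	UCA(S)	55	2.01	UAA	263	2.10	UGA(W)	32	0.26
UUG(L)	53	0.75	UCG(S)	7	0.26	UAG	81	0.65	UGG(W)	25	1.00
CUU(L)	53	0.75	CCU(P)	18	0.87	CAU(H)	69	1.21	CGU(R)	14	0.78
CUC(L)	23	0.32	CCC(P)	29	1.40	CAC(H)	45	0.79	CGC(R)	6	0.33
CUA(L)	78	1.10	CCA(P)	27	1.30	CAA(Q)	110	1.41	CGA(R)	7	0.39
CUG(L)	20	0.28	CCG(P)	9	0.43	CAG(Q)	46	0.59	CGG(R)	8	0.44
AUU(I)	168	1.02	ACU(U)	49	1.15	AAU(N)	234	1.34	AGU(S)	29	1.06
AUC(I)	73	0.44	ACC(U)	43	1.01	AAC(N)	114	0.66	AGC(S)	25	0.91
AUA(M)	254	1.54	ACA(U)	67	1.58	AAA(K)	248	1.45	AGA(S)	38	2.11
AUG(M)	59	1.00	ACG(U)	11	0.26	AAG(K)	95	0.55	AGG(S)	35	1.94
GUU(V)	21	1.00	GCU(A)	7	0.80	GAU(D)	56	1.51	GGU(G)	16	1.14
GUC(V)	11	0.52	GCC(A)	8	0.91	GAC(D)	18	0.49	GGC(G)	7	0.50
GUA(V)	40	1.90	GCA(A)	19	2.17	GAA(E)	70	1.33	GGA(G)	14	1.00
GUG(V)	12	0.57	GCG	1	0.11	GAG(E)	35	0.67	GGG(G)	19	1.36
"""


def reference_annotation_table() -> AnnotationTable:
    """The 38-row published annotation (37 genes + A+T-rich region)."""
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "annotation.tsv"
        path.write_text(_ANNOTATION_TSV)
        return read_feature_table(
            path, genome_length=REFERENCE_GENOME_LENGTH,
            genome_id="R_irregulatiter_dentatus",
        )


@lru_cache(maxsize=None)
def reference_codon_usage() -> tuple[dict[str, int], dict[str, float], dict[str, str]]:
    """(counts, printed RSCU, printed amino-acid labels) per RNA codon."""
    counts: dict[str, int] = {}
    printed_rscu: dict[str, float] = {}
    labels: dict[str, str] = {}
    for line in _CODON_TSV.strip().splitlines():
        cells = line.split("\t")
        for g in range(4):
            label, count, r = cells[3 * g : 3 * g + 3]
            codon = label[:3]
            labels[codon] = label[4:-1] if "(" in label else ""
            counts[codon] = int(count)
            printed_rscu[codon] = float(r)
    if len(counts) != 64:
        raise AssertionError("reference codon table must cover all 64 codons")
    return counts, printed_rscu, labels


def reference_codon_counts() -> dict[str, int]:
    """Printed codon counts (all 64 RNA codons)."""
    return dict(reference_codon_usage()[0])
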