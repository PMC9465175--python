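# Methods

This note documents the conventions, models and design choices behind
mitoprofile, in the order of the analysis pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and the circular data model

All coordinates are 1-based inclusive, the convention of published
mitogenome annotation tables. A feature with `start > end` wraps the
circular origin; its length is `(L − start + 1) + end` for genome length
`L`, and wrap arithmetic always requires `L` explicitly. Conversion to
0-based half-open intervals happens only at the Biopython I/O edges
(FASTA/GenBank reading and writing).

`N` is allowed in sequences; it never pairs and never enters composition
percentages (the denominator is the non-N count), so composition remains
well defined on draft sequences. A Unicode minus sign, en-dash/em-dash
location separators and thousands separators ("14,596–16060") are accepted
when parsing printed tables.

The tab-separated annotation dialect mirrors a published gene-arrangement
table byte-for-byte in its header (Gene / Direction / Location / Size (bp)
/ Anticodon / Start codon / Stop codon / Intergenic Nucleotides *). The
printed Size and IGN columns are retained verbatim and *separately* from
the coordinate-derived values, because published tables are not always
internally consistent: several printed sizes in the shipped reference
annotation contradict their own locations, and the printed IGN column
disagrees with coordinate arithmetic in places. Every report therefore
carries both `computed` and (when available) `printed` values, and
summaries take `ign_source`/`size_source` switches instead of silently
endorsing either. Reproduction of the published spacer statistics
(15 regions, 1–9 bp) and the 1,484 bp tRNA total uses the printed columns;
the conservation-of-circumference invariant (Σ sizes + Σ gaps = L) holds
for the computed ones.

The strand convention of the reference table was normalised to explicit
`+`/`-`: in the source, a dash marks the majority (H) strand and a plus
sign the minority (L) strand, which the prose's strand assignments pin
down unambiguously.

## Arrangement statistics

The signed intergenic gap is defined strictly as
`next.start − prev.end − 1` on the circle (0 = abutting, negative =
overlap length negated). A raw gap more negative than either neighbour
could overlap is interpreted as crossing the origin and shifted by `L`.
A single-feature circle reports `ign_next = L − size` with a
degenerate-adjacency flag. The gene-order signature is the rotation of
`name(strand)` tokens starting at an anchor gene (default `trnI`), falling
back to the lexicographically minimal rotation; two genomes share an
arrangement iff their signatures are equal. Percentages in reports are
rounded half-up to 2 decimals.

## Composition and skews

AT skew = (A − T)/(A + T); GC skew = (G − C)/(G + C). Both are computed at
count level and are exactly antisymmetric under reverse complement (a
property test). Published composition tables sometimes print the GC column
with the opposite orientation, (C − G)/(C + G) — the shipped reference
table does — so the orientation is an explicit argument
(`g_minus_c` default; `c_minus_g` reproduces such tables), never a hidden
convention. Operations accept counts or percentages, so a printed table
can be reproduced from its own percentage columns (denominators cancel).

Class rows concatenate reading-strand feature sequences, since skew is
strand-dependent and class-level skews are conventionally reported on the
reading strand. Rounding: percentages 2 decimals, skews 3, half-up, at the
report edge only.

## Codon usage

RSCU(c) = count(c) × deg(f) / Σ counts over c's synonymous family f; for
each family with positive total the RSCU values sum to the degeneracy
exactly (pre-rounding). CDspT(group) = 1000 × group count / total. Named
two-fold/four-fold split groups follow the field's usage: Leu2 = {UUA,UUG},
Leu1 = CUN, Ser1 = {AGU,AGC}, Ser2 = UCN, Arg1 = CGN, Arg2 = {AGA,AGG}.

Two family partitions ship, built from Biopython's genetic-code tables:
`standard` (Ser 6-fold UCN+AGY, Arg 6-fold CGN+AGR, AUA in 3-fold Ile, UGA
in the stop family) and `invertebrate_mito` (AGR → Ser, AUA → Met, UGA →
Trp). The default for reproducing the shipped reference codon-usage table
is the standard code: its printed RSCU column is arithmetically consistent
only with that partition (e.g. AGA: 38×6/108 = 2.11; UGA: 32×3/376 = 0.26),
despite mitochondrial amino-acid labels. Reports always name the partition
used. Stop codons are counted in the usage table (reference counts include
large UAA/UAG rows); terminal classification treats a trailing `T` or `TA`
as a partial stop completed to UAA by transcript polyadenylation.
Rounding half-up: RSCU 2 decimals, CDspT 1 decimal.

## Control-region repeat detectors

Three detectors, all maximal by construction and each verified against a
naive quadratic oracle in the test suite:

* **Homopolymers** — maximal single-base runs, default minimum 10 bp
  (the features of interest are a ~19 bp poly-T and a terminal poly-A).
* **Microsatellites** — maximal period-u runs trimmed to whole copies,
  default unit 2 bp and ≥ 5 copies; the unit is reported as its
  lexicographically least rotation (resolving the TA/AT phase ambiguity
  deterministically), and single-base units are excluded (a (TT)n is a
  homopolymer).
* **Direct repeats** — maximal same-strand repeated substrings, default
  ≥ 30 bp, found by seeding on shared k-mers and extending left/right with
  explicit character comparison (collision-proof; at control-region sizes
  asymptotics are irrelevant and correctness paramount). Each maximal
  occurrence pair is reported once with both starts; overlapping
  occurrences are allowed — note this means periodic sequences legitimately
  contain many self-overlapping repeats. Inverted repeats are out of scope.

Coordinates are region-relative 1-based, with genome-absolute starts added
in reports.

## Junction windows and motifs

Windows are anchored on annotation coordinates, not on alignment: the
window covers the last `flank_a` bases of the upstream gene through the
first `flank_b` bases of the downstream gene on the *reading strand of the
upstream gene* (defaults 15/15, maximum separation 50 bp). Overlaps are
handled by coordinate arithmetic, so shared bases appear once and the
window length is `flank_a + flank_b + gap`. Published junction motifs vary
by a base between a figure and its caption in the source literature, so
motifs are configuration values, never hard-coded. Consensus uses the
per-column modal base, ties broken A < C < G < T.

## tRNA cloverleaf heuristic

The claims of interest are arm presence and stem pair classes, not free
energies, so folding is an auditable anchored search rather than
thermodynamic prediction:

1. candidate anticodon arms: stems of 4–5 pairs around a 7-nt loop, the
   expected anticodon (from the annotation when available) required at
   loop positions 3–5;
2. acceptor stem: best pairing of the 5′ 1–7 region against the 3′ end
   (7 pairs, ≤ 2 non-pairs, 0–2 unpaired trailing nucleotides);
3. DHU arm (stem 3–4, loop 4–12) searched between acceptor and anticodon
   arms; TΨC arm (stem 4–5, loop 3–9) between anticodon arm and the 3′
   acceptor side — non-crossing by regionalisation;
4. score 3·WC + 2·GU − 1·mismatch over all stems, at most one mismatch per
   stem; best assembly wins, ties broken leftmost start, then longest
   stem, then longest loop.

All weights and minima are exposed in `FoldParams`; they are this
package's choices, with the 3/2/−1 weights ordering Watson–Crick above
wobble above mismatch at round numbers. An arm with no qualifying stem is
reported absent — the situation of mitochondrial tRNAs that have lost the
TΨC or DHU arm. Folding is deterministic; pair classification (WC / G·U
wobble / mismatch, with a positional mismatch list) is a separate,
reusable step.

## Synthetic mitogenome generator

The generator lays the annotation skeleton first and builds sequence to
match it, so the manifest is exact rather than estimated. Defaults emulate
a walking-stick-insect mitogenome: the ancestral insect gene order
(13 PCGs, 22 tRNAs, 2 rRNAs, control region, ~16.2 kb realized), PCG
lengths near published ones adjusted to codon frame, codon draws weighted
by the shipped reference codon counts, ATN/TTA starts and TAA or partial-T
stops per gene, an ATGATAA motif shared across a 7 bp atp8/atp6 overlap,
a TTAACTA motif in a 7 bp trnS2/nad1 spacer, a 1,465 bp control region at
87.06% A+T carrying a 19 bp poly-T, a (TA)10 microsatellite, a terminal
12 bp poly-A and two > 30 bp segments each planted twice, rRNAs at 81.66%
A+T, and trnH/trnM/trnF built without the TΨC arm.

Design choices that make the manifest exactly recoverable:

* **Guard bases.** Every control-region plant is flanked by C/G guards
  (different guards on the two occurrences of a repeat segment), so each
  planted feature is maximal exactly at its planted coordinates.
* **Exact-count filler.** rRNA and control-region filler is a shuffled
  multiset with largest-remainder base counts, hitting the class A+T
  target deterministically; control-region filler chunks are redrawn if
  they contain a homopolymer ≥ 8 or a dinucleotide tandem ≥ 4 copies
  (safely below the detector minima of 10 and 5).
* **Identifiable tRNAs.** Unpaired tRNA regions (loops, spacers, variable
  loop) are drawn from {A, C}, which pair with neither each other nor
  themselves, stems are aperiodic at shifts 1–2 (a TTTT or TATA stem pairs
  its own displaced complement), and each drawn tRNA is verified against
  the default folding heuristic and redrawn on the rare residual
  ambiguity. Planted arms are therefore the unique best-scoring fold by
  construction — under the default `FoldParams`; custom folding
  parameters void that guarantee.
* **Overlaps share sequence**, with the downstream gene owning the shared
  bases (written last). The default overlap set is the atp8/atp6 motif
  overlap only, whose ATGATAA ending keeps the upstream gene's in-frame
  TAA stop intact; arbitrary overlaps are supported in configuration but
  can overwrite an upstream gene's planted tail.
* Determinism: one `numpy` generator seeded from the config; identical
  config + seed gives byte-identical FASTA and manifest.

What the generator does **not** emulate: mutation/selection or any
evolutionary process, sequencing reads, Markov/base-stacking structure in
non-coding filler, biased stop-codon context, or genome-scale repeats
outside the control region. Passing round-trip tests therefore shows the
analysis modules are correct against known ground truth, not that real
mitogenomes obey these simplifications.

## Problem sizes and numerical conventions

All analyses are desk-scale: single genomes of ~16 kb, 22 tRNAs of
55–95 nt, control regions of ~1.5 kb. The test suite exercises round-trip
recovery on seeds 1–5 (full pipeline) and arm recovery on 220 tRNAs across
seeds 1–10 at a ≥ 95% bar; oracle comparisons for the repeat detectors run
on random strings up to 2 kb, direct-repeat oracle comparisons on strings
up to 800 bp plus the full synthetic control region. Rounding is half-up
(away from zero) at report edges only; unrounded values are carried
internally everywhere.

## Known limitations

* The folding heuristic has no thermodynamics; unusual tRNAs with long
  variable arms (some Ser1 tRNAs) may fold with a displaced TΨC arm.
* Direct-repeat reporting is pairwise; a segment occurring k > 2 times
  yields one feature per maximal pair rather than one k-copy feature.
* GenBank support covers the LOCUS/FEATURES/ORIGIN subset with
  CDS/tRNA/rRNA/misc_feature/D-loop keys and origin-spanning joins; exotic
  location operators are not parsed.
* The printed-versus-computed discrepancies of the shipped reference
  annotation are reported, not adjudicated: the package deliberately
  refuses to guess which of a contradictory size/coordinate pair is right.
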