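# Methods

## Motif model and matching semantics

A putative G-quadruplex (pG4) is predicted purely from sequence: runs of
guanines ("stems", each contributing one strand of the quartet stack)
separated by short loops. The perfect pattern `(G{3,}L{1,7}){3,}G{3,}`
requires at least four stems of ≥3 G and loops of 1–7 bp; the multimeric
variant requires ≥8 stems. Matching semantics follow the quadparser
lineage exactly:

* **Leftmost, greedy, non-overlapping per strand.** The scanner uses the
  regex engine's greedy matching and resumes at each match end, so any
  continuous G4-forming stretch counts once. We verified on randomized
  sequences (and assert in the test suite) that this equals the
  leftmost-longest resolution of an exhaustive substring-testing
  enumerator.
* **Loops are unconstrained in composition** — they may contain G and N.
  A consequence worth knowing: a pure run of ≥15 G matches (stems of 3
  separated by 1-G loops). G-runs themselves contain only literal `G`;
  an `N` (assembly gap) terminates a stem and can never fabricate one.
* **Antisense screening** matches the complementary C-pattern on the
  forward sequence, reporting `strand='-'` with forward coordinates and
  the motif sequence reverse-complemented (G-rich, 5′→3′ on the folding
  strand). Forward and reverse motifs may overlap each other.
* **Stem counting** (`count_stems`) reports the maximal number of stems
  over all full-span parses — "each G-run and the repeat count extended
  maximally" — computed by dynamic programming and cross-checked against
  exhaustive parse enumeration. Multimeric totals are produced by an
  independent ≥8-stem scan, and multimeric spans are *not* removed from
  the perfect scan's output.
* Input is uppercased at load; soft-masking is ignored (no masking rule is
  part of the model). Characters outside A/C/G/T/N are rejected with the
  offending position.

## Imperfect (bulged) motifs

The imperfect search targets three-quartet quadruplexes whose stems may be
interrupted: a stem is 3–4 guanines either contiguous (a sub-run of a
longer G-run qualifies) or split into two blocks by exactly one bulge of
1–2 non-G bases; `-g` values above one bulge per stem are not supported.
Loops are 1–`max_loop` bp (7 regular, 12 long-loop); at least four stems
per motif. Bulge bases must be non-G because a G would extend the block —
this also prevents degenerate decompositions.

For every start position the scanner computes the maximal end over all
stem/loop chains (a right-to-left DP, JIT-compiled with numba; ~1 s for a
10-Mb chromosome). Since every valid interval starting at `s` is contained
in the maximal one, merging these per-start candidates (union of
overlapping or book-ended intervals, strictly within strand) yields exactly
the union of *all* valid motif intervals; the tests assert equality with a
brute-force recursive enumerator. Candidate-level tilings are not unique,
so equivalence is defined — and asserted — post-merge only. The reported
`n_stems` is the stem count of a maximal-end chain; `n_candidates` counts
the collapsed per-start candidates.

## Gene features, profiles, peaks

Coordinates are 0-based half-open everywhere internally and in BED output;
GFF3 is converted on read (gffutils, first transcript per gene in file
order). Overlap always means ≥1 shared base. Gene categories are
gene-oriented: 1-kb/500-bp upstream and downstream flanks, gene body,
first vs later CDS blocks, first vs later introns (first-block assignment
wins within a gene when a motif spans both). A gene "has a G4" when its
body ±500 bp overlaps a motif; densities are reported for gene bodies and
for bodies ±500 bp separately, since both framings are in common use.

Positional frequency anchors a ±`half_width` (default 5000 bp) window at
the start codon (= first CDS start) or the first intron's first base,
orients offsets by gene strand (negative = 5′ of the anchor), and tallies
motif-base coverage per offset, split into gene-sense and gene-antisense.
A per-motif-start mode is available behind a flag. Dividing by the number
of anchored regions gives the plotted frequency; the "per Mb" scale is
that fraction ×10⁶ (both are emitted, since published y-axes are not
always defined formulaically). Windows truncated by a chromosome end are
clipped.

Smoothing is a centred moving mean with the window shrinking at the array
edges (no zero-padding, which would fabricate boundary dips); the window
must be odd and 1 is the identity. Peak counting in tests and the
acceptance script uses `scipy.signal.find_peaks` with height ≥25% and
prominence ≥20% of the profile maximum — on scrubbed synthetic profiles
this isolates exactly the planted enrichment zones.

The three peak gene sets use gene-antisense motifs only: peak1 =
gene-oriented [−250, 0) upstream of the start codon, peak2 = [0, +250),
peak3 = first 100 bp of intron 1 (multi-exon genes only); sets may
intersect. Genome histograms split each chromosome into `n_bins` (default
1000) equal-width bins, last bin absorbing the remainder, binning each
feature by its start — the deterministic Circos-histogram convention.

## Enrichment and GO statistics

Interval shuffling preserves every region's length, draws the chromosome
with probability proportional to its length among chromosomes the region
fits on, and places the start uniformly; shuffled intervals may overlap
each other and no exclusion mask is applied. Fold enrichment is observed
overlap / mean shuffled overlap (one replicate reproduces the classical
procedure; `n_reps` exposes the shuffle variance). Because lengths are
preserved, count-ratio and density-ratio folds coincide. The random
background generates three iid uniform A/C/G/T datasets (≥100 kb each),
scans each, and returns the median density with all three for audit.

GO association runs a Pearson chi-square (no continuity correction by
default; Yates behind a flag) per term on (G4-gene × term) 2×2 tables,
flagging terms with any expected cell <5; over-representation uses the
hypergeometric upper tail P(X ≥ k). Both apply Benjamini–Hochberg FDR
across tested terms. Terms are tested exactly as annotated — no ancestor
propagation up the ontology graph.

## SNP disruption

Classification applies to perfect-pattern motifs. A SNP in the ±10-bp
flank, or in a loop of the maximal stem parse, is `loop_or_flank`.
Otherwise the alternate allele is written into the motif's ±10-bp
neighbourhood and the window rescanned on the motif's strand: if a perfect
motif still overlaps the original span the substitution is
`stem_tolerated` (redundant G-runs slide over the lesion), else
`stem_disruptive`. Identical ref/alt alleles therefore can never be
disruptive. SNP–motif intersection is computed on each strand's intervals
as reported; paired rows carry the offset within the motif interval.

## Synthetic genomes

The generator emulates the data shape the analyses assume, not sequence
biology: iid background at a configurable GC (default 0.44, a typical
cereal-genome value), non-overlapping gene models with CDS == exons (no
UTRs, as in many plant annotations; exons 300–600 bp, introns 300–800 bp,
1–4 exons, multi-exon fraction 0.69), TEs as interval labels only (default
0.3 of the genome, intergenic, with family labels weighted toward
unclassified/Gypsy/Copia LTR retrotransposons and CACTA elements), SNPs
planted per zone (stem/loop/flank/intergenic), and GO terms assigned
independently of G4 status (prevalence U(0.05, 0.4) per term) so GO tests
have a true null.

The background is **scrubbed** to a fixpoint: every spurious perfect and
imperfect motif on either strand is broken by mutating the middle base of
the middle G-run (C-run for antisense hits) to T (A), which splits a long
chain into halves and converges in O(log stems) passes; the iteration
bound of 10 is asserted. Planted motifs use minimal sequences (15-bp
perfect, 31-bp 8-stem multimeric, 17-bp single-bulge imperfect) written
over the background with 8-bp AT buffers on both sides — longer than any
loop — so rescanning recovers exactly the planted coordinates. Default
placements are antisense perfect motifs at the three peak zones with
per-gene probabilities 0.6/0.3/0.1 (upstream-biased, as observed in real
metagene profiles); uniform and gene-body scatter placements support
enrichment calibration. Everything is deterministic under the spec seed,
and a truth ledger records every planted object with zone labels.

What passing these tests shows — and does not. Exact recovery and peak
equality demonstrate coordinate bookkeeping, strand handling and category
logic end-to-end; they do not validate motif calls against folded
structures, real repeat landscapes, GC heterogeneity, or annotation noise,
none of which the generator models. Long-loop (12-bp) spurious motifs are
scrubbed only when `imperfect_long` is included in `scrub_classes`.

## Problem sizes and numerical choices

The standard validation cohort is 10 Mb (2×5 Mb) with 500 genes — large
enough for ~500 planted motifs and stable shuffle statistics, small enough
to regenerate fresh in well under a minute. Scanner cross-checks use 200
seeded 2-kb sequences (perfect) and 100 seeded 500-bp sequences
(imperfect) against brute-force enumerators; GO null calibration uses
2,000 independent terms over 3,000 genes with a KS test at α = 0.01.
Shuffle calibration uses 50 replicates; the genic-planting fold is
compared to its analytic expectation (1 / gene coverage) within three
delta-method standard errors. Chi-square statistics are validated against
the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) to machine precision.

## Known limitations

* No thermodynamic or structural scoring (G4Hunter-type scores, RNA G4
  folding) — scanning is purely pattern-based.
* Imperfect stems support at most one bulge; mismatch-containing stems and
  two-quartet (G2) motifs are out of scope.
* Whether candidate merging should ever cross strands is treated as
  settled within-strand; strand-collapsed interval unions are available to
  callers but not the default.
* GO analysis ignores the ontology DAG.
* The SNP classifier assumes biallelic single-base substitutions and
  perfect-pattern motifs.
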