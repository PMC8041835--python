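# g4atlas

Genome-wide G-quadruplex (G4) motif discovery and distribution analysis for
plant-scale genomes.

G-quadruplexes are four-stranded nucleic-acid structures formed by stacked
G-quartets in guanine-rich sequence. Putative G4 motifs cluster around gene
regulatory landmarks — immediately upstream of the start codon (5′ UTR), in
the first CDS, and at the first intron's splice donor, largely on the
antisense strand — and their positions, disruption by variants, and
associated gene functions are of direct interest in regulatory genomics.
`g4atlas` provides the full computational pipeline for this kind of study:
motif scanning, gene-feature assignment, metagene profiling, enrichment
testing, SNP-disruption analysis, GO statistics, and a synthetic-genome
generator for end-to-end validation without any external download.

## The core patterns and statistics

* **Perfect motifs** match `(G₃₊L₁₋₇)₃₊G₃₊`: at least four runs ("stems") of
  ≥3 guanines separated by loops of 1–7 arbitrary bases. Matching is
  leftmost, greedy and non-overlapping per strand (the quadparser
  convention), so a continuous G4 stretch is counted once. The antisense
  strand is screened with the complementary C-pattern. **Multimeric**
  motifs require ≥8 stems (`(G₃₊L₁₋₇)₇₊G₃₊`).
* **Imperfect motifs** allow each stem of 3–4 guanines to carry one bulge of
  1–2 non-G bases, with loops up to 7 bp (or 12 bp in the long-loop
  variant); overlapping candidates merge into single reported motifs.
* **G4 density** is motifs overlapping a region set per Mb of unioned span;
  **G4 frequency** is per-position motif-base coverage around an anchor
  (start codon or intron-1 start), gene-oriented and split by gene-relative
  strand, divided by the number of anchored regions.
* **Enrichment** compares observed overlap of a region set with motifs to
  the overlap after length-preserving uniform shuffling of the regions
  (fold = observed/shuffled), plus iid-uniform random sequence backgrounds
  (median density of three datasets).
* **GO association** uses a per-term Pearson chi-square on the 2×2 table of
  G4-gene status × term membership; **GO over-representation** uses the
  hypergeometric upper tail; both are BH-FDR corrected.
* **SNP disruption**: a SNP in a loop or flank leaves the quartet stack
  intact; a SNP in a stem is applied to the sequence and the neighbourhood
  rescanned — if no perfect motif survives on that strand the variant is
  classified stem-disruptive, otherwise redundant G-runs rescued it.

## Worked example

`examples/04_metagene_profile.py` plants antisense motifs at the three peak
zones (per-gene probabilities 0.6 / 0.3 / 0.1) on a 1.6-Mb two-chromosome
synthetic genome, rescans it, and profiles ±5 kb around the start codon:

```
profile over 120 genes; antisense maximum at offset -250 bp
window    1 bp: 2 peak(s) at offsets [-243, 132]
window   99 bp: 2 peak(s) at offsets [-243, 132]
window  199 bp: 2 peak(s) at offsets [-243, 132]
window  999 bp: 1 peak(s) at offsets [173]

peak gene-set sizes: {'peak1': 79, 'peak2': 33, 'peak3': 16}
```

The antisense frequency peaks exactly where motifs were planted (upstream
−250 bp and +125 bp into the first CDS; plateau centres reported at −243
and +132). With a 99-bp moving average both peaks survive; with a 999-bp
window they fuse into a single apparent peak near the start codon — the
smoothing artifact that makes window choice critical when reading published
metagene profiles. `peak1/peak2/peak3` are the gene sets carrying an
antisense motif in [−250,0), [0,+250) and the first 100 bp of intron 1.

The other examples cover scanning (`01`, `02`), feature assignment and
densities (`03`), shuffle enrichment and random backgrounds (`05`), GO
statistics (`06`) and SNP disruption (`07`); each prints its results with a
short interpretation.

A thin CLI mirrors the library:

```bash
g4atlas simulate --seed 5 --out-dir sim/
g4atlas scan --fasta sim/genome.fa --mode perfect --out motifs.bed
g4atlas profile --motifs motifs.bed --genes sim/genes.gff3 --window 99 --out prof.tsv
```

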