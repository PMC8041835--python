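"""Metagene motif-frequency profile around the start codon.

Plants antisense motifs at the three peak zones (upstream -250, first CDS
+125, intron-1 start), profiles a +-5 kb window per gene, and shows how a
wide moving-average window fuses the two start-codon peaks into one.
"""

import numpy as np
from scipy.signal import find_peaks

from g4atlas import (
    moving_average,
    peak_gene_sets,
    plant_profile_cohort,
    positional_frequency,
    scan_both_strands,
)

ds = plant_profile_cohort(n_genes=120, chrom_lengths=(800_000, 800_000), seed=2)
motifs = [m for rec in ds.records for m in scan_both_strands(rec)]

prof = positional_frequency(motifs, ds.truth.genes, "start_codon", half_width=5000)
anti = prof.counts_antisense.astype(float)
print(f"profile over {prof.n_regions} genes; antisense maximum at offset "
      f"{prof.offsets[np.argmax(anti)]} bp")

for window in (1, 99, 199, 999):
    sm = moving_average(anti, window)
    pk, _ = find_peaks(sm, height=0.25 * sm.max(), prominence=0.2 * sm.max())
    print(f"window {window:4d} bp: {len(pk)} peak(s) at offsets "
          f"{[int(prof.offsets[i]) for i in pk]}")

peaks = peak_gene_sets(motifs, ds.truth.genes)
print("\npeak gene-set sizes:", {k: len(v) for k, v in peaks.items()})
print(
    "\nSmall windows resolve the two peaks flanking the start codon; a\n"
    "999-bp window averages them into a single apparent peak."
)
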