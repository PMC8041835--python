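"""Scan a sequence for perfect and multimeric G-quadruplex motifs.

The canonical pattern is (G3+ L1-7)3+ G3+: four or more runs of >=3 G
separated by 1-7 bp loops. The antisense strand is screened with the
complementary C-pattern; multimeric motifs need >= 8 G-runs.
"""

from g4atlas import SequenceRecord, scan_both_strands

seq = (
    "TTATG" + "GGGAGGGTGGGAGGG"          # perfect motif, sense strand
    + "ATATATAT" + "CCCTCCCACCCTCCC"      # perfect motif, antisense strand
    + "ATATATAT" + "GGGA" * 7 + "GGG"     # 8 stems: multimeric
    + "TTACA"
)
rec = SequenceRecord("demo", seq)

print("perfect scan (both strands):")
for m in scan_both_strands(rec, "perfect"):
    print(f"  [{m.start:3d},{m.end:3d}) {m.strand}  {m.n_stems} stems  {m.motif_seq}")

print("multimeric scan (>= 8 stems):")
for m in scan_both_strands(rec, "multimeric"):
    print(f"  [{m.start:3d},{m.end:3d}) {m.strand}  {m.n_stems} stems")

print(
    "\nEach line is one non-overlapping motif interval (0-based, half-open);\n"
    "minus-strand motifs are reported 5'->3' on the strand that folds."
)
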