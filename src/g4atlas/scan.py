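"""Perfect and multimeric G-quadruplex motif scanning.

The canonical putative-G4 pattern is ``(G{3+}L{1-7}){3+}G{3+}``: at least
four runs ("stems") of >=3 guanines separated by loops of 1-7 arbitrary
bases. Matching follows the quadparser lineage: leftmost, greedy (each
quantifier extended maximally, backtracking as the regex engine does) and
non-overlapping within a strand (the search resumes at the previous match
end), so any continuous G4 stretch is counted once. Multimeric motifs use
the same pattern with at least eight stems.

Loops may contain any base including G and N; G-runs contain only literal
``G``, so an assembly-gap ``N`` terminates a stem and never fabricates one.
The antisense strand is screened by matching the complementary C-pattern on
the forward sequence and reporting ``strand='-'`` with the motif sequence
reverse-complemented (G-rich, 5'->3' on the folding strand).
"""

from __future__ import annotations

import re
from functools import lru_cache

from .records import G4Motif, SequenceRecord, revcomp

LOOP_MIN = 1
LOOP_MAX = 7
STEM_MIN_G = 3

MULTIMERIC_MIN_STEMS = 8


@lru_cache(maxsize=None)
def _pattern(base: str, min_stems: int, max_loop: int = LOOP_MAX) -> re.Pattern:
    return re.compile(
        "(?:%s{%d,}[ACGTN]{%d,%d}){%d,}%s{%d,}"
        % (base, STEM_MIN_G, LOOP_MIN, max_loop, min_stems - 1, base, STEM_MIN_G)
    )


def greedy_stem_parse(
    motif_seq: str,
    min_stems: int = 4,
    max_loop: int = LOOP_MAX,
    base: str = "G",
) -> list[tuple[int, int]]:
    """Decompose a full motif span into stems, maximising the stem count.

    The greedy reading of the pattern extends every G-run and the repeat
    count maximally, so the parse uses as many stems as the span admits;
    among maximal-count parses the earliest stems are extended longest (with
    the shortest loops that preserve the count). Returns the stem intervals
    ``[(start, end), ...]`` (0-based, half-open, relative to ``motif_seq``);
    gaps between stems are loops. Raises ``ValueError`` if the sequence does
    not match the pattern over its full span.
    """
    n = len(motif_seq)
    # maximal run of `base` starting at each position
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if motif_seq[i] == base else 0

    NEG = -(10**9)
    best: dict[int, int] = {}

    def units(i: int) -> int:
        """Max number of stems in a chain starting at i that ends exactly at n."""
        if i in best:
            return best[i]
        r = run[i]
        res = NEG
        if r >= STEM_MIN_G:
            if i + r == n:
                res = 1
            for stem in range(STEM_MIN_G, r + 1):
                j = i + stem
                if j >= n:
                    break
                for loop in range(LOOP_MIN, max_loop + 1):
                    m = j + loop
                    if m < n:
                        res = max(res, units(m) + 1)
        best[i] = res
        return res

    total = units(0)
    if total < min_stems:
        raise ValueError("sequence does not match the G4 pattern over its full span")
    stems: list[tuple[int, int]] = []
    i, remaining = 0, total
    while remaining > 0:
        r = run[i]
        if remaining == 1:
            # terminal stem consumes the rest of the span (all base)
            assert i + r == n
            stems.append((i, n))
            break
        placed = False
        for stem in range(r, STEM_MIN_G - 1, -1):  # longest stem first
            j = i + stem
            if j >= n:
                continue
            for loop in range(LOOP_MIN, max_loop + 1):  # shortest loop first
                m = j + loop
                if m < n and units(m) == remaining - 1:
                    stems.append((i, j))
                    i, remaining, placed = m, remaining - 1, True
                    break
            if placed:
                break
        assert placed
    return stems


def count_stems(motif_seq: str, base: str = "G", min_stems: int = 4) -> int:
    """Number of stems in the maximal greedy parse of a perfect-pattern motif."""
    return len(greedy_stem_parse(motif_seq, min_stems=min_stems, base=base))


def _scan_base(
    record: SequenceRecord,
    base: str,
    min_stems: int,
    motif_class: str,
    max_loop: int = LOOP_MAX,
) -> list[G4Motif]:
    pat = _pattern(base, min_stems, max_loop)
    out = []
    for m in pat.finditer(record.seq):
        s, e = m.span()
        if base == "G":
            strand, mseq = "+", m.group(0)
        else:
            strand, mseq = "-", revcomp(m.group(0))
        n_stems = count_stems(mseq, base="G", min_stems=min_stems)
        out.append(
            G4Motif(
                chrom=record.id,
                start=s,
                end=e,
                strand=strand,
                motif_seq=mseq,
                n_stems=n_stems,
                motif_class=motif_class,
            )
        )
    return out


def scan_perfect(record: SequenceRecord, min_stems: int = 4) -> list[G4Motif]:
    """Forward-strand perfect G4 motifs, leftmost-greedy non-overlapping.

    ``min_stems`` is the minimum number of G-runs per motif (default 4,
    i.e. three stacked quartets from runs of >=3 G).
    """
    if min_stems < 2:
        raise ValueError("min_stems must be >= 2")
    return _scan_base(record, "G", min_stems, "perfect")


def scan_multimeric(record: SequenceRecord) -> list[G4Motif]:
    """Forward-strand motifs with at least eight G-stems (multimeric G4s)."""
    return _scan_base(record, "G", MULTIMERIC_MIN_STEMS, "multimeric")


def scan_both_strands(
    record: SequenceRecord, mode: str = "perfect", min_stems: int | None = None
) -> list[G4Motif]:
    """Scan both strands; antisense via the C-pattern on the forward sequence.

    Returns the union of the forward G-pattern scan and the C-pattern scan
    (reported with ``strand='-'``), sorted by (start, strand). Motifs on
    opposite strands may overlap each other; within a strand they never do.
    """
    if mode == "perfect":
        k = 4 if min_stems is None else min_stems
        cls = "perfect"
    elif mode == "multimeric":
        k = MULTIMERIC_MIN_STEMS
        cls = "multimeric"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fwd = _scan_base(record, "G", k, cls)
    rev = _scan_base(record, "C", k, cls)
    return sorted(fwd + rev, key=lambda m: (m.start, m.strand))
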