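"""Independent brute-force oracles used to validate the scanners.

These deliberately avoid the production code paths: the perfect-motif
oracle tests every candidate substring against an anchored pattern and
resolves non-overlap leftmost-longest; the imperfect oracle enumerates all
stem/loop decompositions recursively; the stem-count oracle enumerates all
parses of a motif and selects the greedy one by explicit priority order.
"""

from __future__ import annotations

import re
from functools import lru_cache

import numpy as np


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def brute_force_scan(seq: str, min_stems: int = 4, base: str = "G") -> list[tuple[int, int]]:
    """Leftmost-longest non-overlapping matches of the canonical pattern.

    Tests every candidate substring (delimited by >=3 runs of ``base``)
    against the anchored pattern; at each leftmost matching start the
    longest match wins and the search resumes at its end.
    """
    n = len(seq)
    pat = re.compile(
        "(?:%s{3,}[ACGTN]{1,7}){%d,}%s{3,}" % (base, min_stems - 1, base)
    )
    run3 = base * 3
    cand_starts = [i for i in range(n - 2) if seq[i : i + 3] == run3]
    cand_ends = [j for j in range(3, n + 1) if seq[j - 3 : j] == run3]
    best_end: dict[int, int] = {}
    for s in cand_starts:
        for e in cand_ends:
            if e - s >= 4 * min_stems - 1 and pat.fullmatch(seq, s, e):
                if e > best_end.get(s, -1):
                    best_end[s] = e
    out = []
    pos = 0
    for s in sorted(best_end):
        if s >= pos:
            e = best_end[s]
            out.append((s, e))
            pos = e
    return out


def brute_force_both_strands(seq: str, min_stems: int = 4) -> set[tuple[int, int, str]]:
    return {(s, e, "+") for s, e in brute_force_scan(seq, min_stems, "G")} | {
        (s, e, "-") for s, e in brute_force_scan(seq, min_stems, "C")
    }


def brute_force_imperfect_merged(seq, params, base="G"):
    """Union of all valid imperfect-motif intervals by exhaustive recursion."""
    n = len(seq)
    ism = [c == base for c in seq]

    def stems_at(i):
        out = set()
        for g in range(params.stem_min, params.stem_max + 1):
            if i + g <= n and all(ism[i : i + g]):
                out.add(i + g)
        if params.max_bulges_per_stem:
            for a in range(1, params.stem_max):
                if i + a > n or not all(ism[i : i + a]):
                    break
                for b in range(1, params.max_bulge_len + 1):
                    if i + a + b > n or any(ism[i + a : i + a + b]):
                        continue
                    for c in range(max(params.stem_min - a, 1), params.stem_max - a + 1):
                        e = i + a + b + c
                        if e <= n and all(ism[i + a + b : e]):
                            out.add(e)
        return out

    @lru_cache(maxsize=None)
    def ends(i, k):
        res = set()
        for j in stems_at(i):
            if k <= 1:
                res.add(j)
            for l in range(1, params.max_loop + 1):
                if j + l < n:
                    res |= ends(j + l, max(k - 1, 1))
        return frozenset(res)

    intervals = []
    for s in range(n):
        for e in ends(s, params.min_stems):
            intervals.append((s, e))
    ends.cache_clear()
    intervals.sort()
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def max_stems_by_enumeration(seq: str, min_stems: int = 4, max_loop: int = 7) -> int:
    """Maximal stem count over ALL full-span parses, by exhaustive recursion."""
    n = len(seq)
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if seq[i] == "G" else 0
    counts: list[int] = []

    def rec(i, count):
        r = run[i]
        if r < 3:
            return
        for stem in range(r, 2, -1):
            j = i + stem
            if j == n:
                if count + 1 >= min_stems:
                    counts.append(count + 1)
                continue
            for loop in range(max_loop, 0, -1):
                m = j + loop
                if m < n:
                    rec(m, count + 1)

    rec(0, 0)
    if not counts:
        raise ValueError("no full-span parse")
    return max(counts)


def naive_overlap_categories(motif, gene, flank_small=500, flank_large=1000):
    """O(categories) per-pair overlap check used to validate assign_motifs."""
    s, e = gene.start, gene.end
    if gene.strand == "+":
        regions = {
            "upstream_1k": (s - flank_large, s),
            "flank5_500": (s - flank_small, s),
            "downstream_1k": (e, e + flank_large),
            "flank3_500": (e, e + flank_small),
        }
    else:
        regions = {
            "upstream_1k": (e, e + flank_large),
            "flank5_500": (e, e + flank_small),
            "downstream_1k": (s - flank_large, s),
            "flank3_500": (s - flank_small, s),
        }
    pairs = list(regions.items()) + [("gene_body", (s, e))]
    for i, (bs, be) in enumerate(gene.cds_blocks):
        pairs.append((f"cds_{'first' if i == 0 else 'rest'}", (bs, be)))
    for i, (bs, be) in enumerate(gene.introns()):
        pairs.append((f"intron_{'first' if i == 0 else 'rest'}", (bs, be)))
    cats = {
        name
        for name, (a, b) in pairs
        if motif.start < b and motif.end > max(a, 0)
    }
    for stem in ("cds", "intron"):
        if f"{stem}_first" in cats:
            cats.discard(f"{stem}_rest")
    return cats
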