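"""Bulged-imperfect G-quadruplex motif enumeration.

An imperfect motif is a chain of at least ``min_stems`` stems joined by
loops of 1..``max_loop`` arbitrary bases, where a stem is either a
contiguous block of ``stem_min``..``stem_max`` guanines (a sub-run of a
longer G-run is allowed) or two G-blocks totalling that many guanines
separated by a single bulge of 1..``max_bulge_len`` non-G bases. The default
parameterisation (stems of 3-4 G, loops <=7 bp, one bulge of <=2 bp per
stem) targets three-quartet quadruplexes with one interrupted strand; the
"long loop" variant relaxes loops to 12 bp. Perfect (bulge-free) motifs
satisfy the definition and are included.

For every position where a chain can start the scanner reports the
maximal-end candidate interval (a dynamic programme over stem/loop
decompositions, JIT-compiled); overlapping or book-ended candidates on the
same strand are then merged into single reported motifs, so the merged
output equals the union of *all* valid motif intervals. The antisense strand
is screened with the complementary C-pattern, exactly as in
:mod:`g4atlas.scan`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .records import G4Motif, MergedMotif, SequenceRecord, revcomp


@dataclass(frozen=True)
class ImperfectParams:
    """Parameters of the bulged-stem search.

    stem_min/stem_max: guanines per stem (a stem uses exactly this many Gs,
    never more, even inside a longer run). max_loop: loop length bound in bp
    (7 regular, 12 long-loop). max_bulges_per_stem: 0 disables bulges, 1
    allows one per stem. max_bulge_len: bulge length bound in bp. min_stems:
    stems per motif.
    """

    stem_min: int = 3
    stem_max: int = 4
    max_loop: int = 7
    max_bulges_per_stem: int = 1
    max_bulge_len: int = 2
    min_stems: int = 4

    def __post_init__(self) -> None:
        if not (1 <= self.stem_min <= self.stem_max):
            raise ValueError("need 1 <= stem_min <= stem_max")
        if self.max_loop < 1 or self.max_bulge_len < 1 or self.min_stems < 2:
            raise ValueError("max_loop, max_bulge_len >= 1 and min_stems >= 2")
        if self.max_bulges_per_stem not in (0, 1):
            raise ValueError("max_bulges_per_stem supports 0 or 1")

    @property
    def motif_class(self) -> str:
        return "imperfect" if self.max_loop <= 7 else "imperfect_long"


LONG_LOOP_PARAMS = ImperfectParams(max_loop=12)


@njit(cache=False)
def _chain_dp(gm, stem_min, stem_max, max_loop, max_bulge, allow_bulge, min_stems):
    """Max chain end (and its stem count) per start position.

    gm: uint8 mask of stem-base positions (G on the forward search, C on the
    antisense search). Returns (maxend, nstems) arrays; maxend[i] == -1 when
    no chain of >= min_stems stems starts at i.
    """
    n = gm.size
    # R[r, i]: max end of a chain from i with >= r+1 stems; S[r, i]: stems used
    R = np.full((min_stems, n + 2 + stem_max + max_bulge), -1, np.int64)
    S = np.zeros((min_stems, n + 2 + stem_max + max_bulge), np.int64)
    # distinct stem-end offsets are bounded by stem_max + max_bulge
    stem_ends = np.empty(stem_max + max_bulge + 4, np.int64)
    for i in range(n - 1, -1, -1):
        if gm[i] == 0:
            continue
        # enumerate stem end positions from i
        ns = 0
        # contiguous stems of stem_min..stem_max bases
        for g in range(stem_min, stem_max + 1):
            if i + g > n:
                break
            ok = True
            for t in range(i, i + g):
                if gm[t] == 0:
                    ok = False
                    break
            if not ok:
                break
            stem_ends[ns] = i + g
            ns += 1
        if allow_bulge:
            # block1 (a) + bulge (b, non-stem bases) + block2 (c), a+c in range
            for a in range(1, stem_max):
                oka = True
                for t in range(i, i + a):
                    if t >= n or gm[t] == 0:
                        oka = False
                        break
                if not oka:
                    break
                for b in range(1, max_bulge + 1):
                    okb = True
                    for t in range(i + a, i + a + b):
                        if t >= n or gm[t] != 0:
                            okb = False
                            break
                    if not okb:
                        continue
                    cmin = stem_min - a if stem_min - a > 1 else 1
                    for c in range(cmin, stem_max - a + 1):
                        e = i + a + b + c
                        if e > n:
                            break
                        okc = True
                        for t in range(i + a + b, e):
                            if gm[t] == 0:
                                okc = False
                                break
                        if not okc:
                            break
                        # dedupe
                        dup = False
                        for q in range(ns):
                            if stem_ends[q] == e:
                                dup = True
                                break
                        if not dup:
                            stem_ends[ns] = e
                            ns += 1
        if ns == 0:
            continue
        for r in range(min_stems):
            best = -1
            bstems = 0
            for q in range(ns):
                j = stem_ends[q]
                if r == 0 and j > best:
                    best = j
                    bstems = 1
                rprev = r - 1 if r > 0 else 0
                for l in range(1, max_loop + 1):
                    m = j + l
                    if m >= n:
                        break
                    cand = R[rprev, m]
                    if cand > best or (cand == best and S[rprev, m] + 1 > bstems):
                        best = cand
                        bstems = S[rprev, m] + 1
            R[r, i] = best
            S[r, i] = bstems
    return R[min_stems - 1, : n + 1].copy(), S[min_stems - 1, : n + 1].copy()


def _scan_strand(seq: str, params: ImperfectParams, stem_base: str) -> list[tuple[int, int, int]]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    gm = (arr == ord(stem_base)).astype(np.uint8)
    maxend, nstems = _chain_dp(
        gm,
        params.stem_min,
        params.stem_max,
        params.max_loop,
        params.max_bulge_len,
        params.max_bulges_per_stem > 0,
        params.min_stems,
    )
    return [
        (int(i), int(maxend[i]), int(nstems[i]))
        for i in np.nonzero(maxend[: len(seq)] >= 0)[0]
    ]


def scan_imperfect(record: SequenceRecord, params: ImperfectParams | None = None) -> list[G4Motif]:
    """Candidate imperfect motifs on both strands (pre-merge).

    One maximal-end candidate per chain start position; use
    :func:`merge_overlapping` to collapse them into reported motifs.
    """
    params = params or ImperfectParams()
    out: list[G4Motif] = []
    for base, strand in (("G", "+"), ("C", "-")):
        for s, e, k in _scan_strand(record.seq, params, base):
            mseq = record.seq[s:e]
            if strand == "-":
                mseq = revcomp(mseq)
            out.append(
                G4Motif(
                    chrom=record.id,
                    start=s,
                    end=e,
                    strand=strand,
                    motif_seq=mseq,
                    n_stems=k,
                    motif_class=params.motif_class,
                )
            )
    return sorted(out, key=lambda m: (m.start, m.strand))


def merge_overlapping(candidates: list[G4Motif], seq: str | None = None) -> list[MergedMotif]:
    """Union overlapping or book-ended candidate intervals, per strand.

    Strands are never merged with each other. ``seq`` (the forward chromosome
    sequence) supplies the merged motif sequence; without it the merged
    ``motif_seq`` is stitched from the candidates where possible.
    """
    if not candidates:
        return []
    chroms = {c.chrom for c in candidates}
    if len(chroms) > 1:
        raise ValueError(f"candidates span multiple chromosomes: {sorted(chroms)}")
    merged: list[MergedMotif] = []
    for strand in ("+", "-"):
        cs = sorted((c for c in candidates if c.strand == strand), key=lambda c: c.start)
        if not cs:
            continue
        cur_s, cur_e, n, stems, cls = cs[0].start, cs[0].end, 1, cs[0].n_stems, cs[0].motif_class
        fwd = {c.start: c for c in cs}

        def emit(s, e, n, stems, cls):
            if seq is not None:
                mseq = seq[s:e]
            elif s in fwd and fwd[s].end == e:
                m = fwd[s].motif_seq
                mseq = m if strand == "+" else revcomp(m)
            else:
                mseq = "N" * (e - s)
            if strand == "-":
                mseq = revcomp(mseq)
            merged.append(
                MergedMotif(
                    chrom=cs[0].chrom, start=s, end=e, strand=strand,
                    motif_seq=mseq, n_stems=stems, motif_class=cls, n_candidates=n,
                )
            )

        for c in cs[1:]:
            if c.start <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, c.end)
                stems = max(stems, c.n_stems)
                n += 1
            else:
                emit(cur_s, cur_e, n, stems, cls)
                cur_s, cur_e, n, stems, cls = c.start, c.end, 1, c.n_stems, c.motif_class
        emit(cur_s, cur_e, n, stems, cls)
    return sorted(merged, key=lambda m: (m.start, m.strand))


def scan_imperfect_merged(
    record: SequenceRecord, params: ImperfectParams | None = None
) -> list[MergedMotif]:
    """Convenience: enumerate candidates and merge them in one call."""
    return merge_overlapping(scan_imperfect(record, params), seq=record.seq)
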