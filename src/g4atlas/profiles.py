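"""Densities, anchored positional profiles, smoothing, peaks, genome bins.

G4 *density* is the number of motifs overlapping a region set, per Mb of
unioned region span. G4 *frequency* is per-position: for every gene a
window of ``2*half_width`` bp is anchored at a landmark (start codon /
first-CDS start, or first-intron start), offsets are gene-oriented
(negative = 5' of the anchor on the gene's sense) and every genomic base
covered by a motif increments the tally at its offset, split by
gene-relative strand (sense = motif strand equals gene strand). Dividing by
the number of anchored regions gives the per-position frequency; the
"per Mb" scale of comparative plots is that fraction times 1e6.

The three enrichment zones defined on the antisense strand are
peak1 = gene-oriented [-250, 0) upstream of the start codon (5' UTR side),
peak2 = [0, +250) (first CDS), and peak3 = the first 100 bp of intron 1
(multi-exon genes only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .records import G4Motif

PEAK1_ZONE = (-250, 0)
PEAK2_ZONE = (0, 250)
PEAK3_LEN = 100

ANCHOR_KINDS = ("start_codon", "cds_start", "intron1_start")


@dataclass
class PositionalProfile:
    """Per-offset motif-overlap tallies around an anchor, per strand class."""

    anchor_kind: str
    half_width: int
    counts_sense: np.ndarray
    counts_antisense: np.ndarray
    n_regions: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width)

    @property
    def counts_both(self) -> np.ndarray:
        return self.counts_sense + self.counts_antisense

    def frequency(self, which: str = "both", normalize: str = "fraction") -> np.ndarray:
        """Normalised per-position frequency.

        ``fraction`` divides the tallies by the number of anchored regions;
        ``per_Mb`` additionally scales by 1e6; ``raw`` returns the tallies.
        """
        counts = {
            "sense": self.counts_sense,
            "antisense": self.counts_antisense,
            "both": self.counts_both,
        }[which]
        if normalize == "raw":
            return counts.astype(float)
        frac = counts / self.n_regions
        if normalize == "fraction":
            return frac
        if normalize == "per_Mb":
            return frac * 1e6
        raise ValueError(f"unknown normalize {normalize!r}")

    def to_frame(self, normalize: str = "fraction") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "sense": self.frequency("sense", normalize),
                "antisense": self.frequency("antisense", normalize),
                "both": self.frequency("both", normalize),
            }
        )


def _anchor_pos(gene: GeneModel, anchor_kind: str) -> int | None:
    if anchor_kind in ("start_codon", "cds_start"):
        return gene.start_codon_pos() if gene.has_cds else None
    if anchor_kind == "intron1_start":
        return gene.intron1_start_pos() if gene.n_exons >= 2 else None
    raise ValueError(f"unknown anchor kind {anchor_kind!r}")


def positional_frequency(
    motifs: list[G4Motif],
    genes: list[GeneModel],
    anchor_kind: str = "start_codon",
    half_width: int = 5000,
    mode: str = "coverage",
) -> PositionalProfile:
    """Tally motif-base coverage per gene-oriented offset around an anchor.

    ``mode='coverage'`` increments every offset a motif covers (the
    frequency definition used throughout); ``mode='start'`` increments only
    the offset of the motif's gene-oriented 5' end. Windows running off a
    chromosome end are truncated to the available span.
    """
    if mode not in ("coverage", "start"):
        raise ValueError(f"unknown mode {mode!r}")
    width = 2 * half_width
    sense = np.zeros(width, dtype=np.int64)
    anti = np.zeros(width, dtype=np.int64)
    by_chrom: dict[str, list[G4Motif]] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)
    for ms in by_chrom.values():
        ms.sort(key=lambda m: m.start)
    n_regions = 0
    for gene in genes:
        try:
            a = _anchor_pos(gene, anchor_kind)
        except ValueError:
            a = None
        if a is None:
            continue
        n_regions += 1
        win_lo, win_hi = a - half_width, a + half_width
        if gene.strand == "-":
            win_lo, win_hi = a - half_width + 1, a + half_width + 1
        for m in by_chrom.get(gene.chrom, ()):
            if m.end <= win_lo:
                continue
            if m.start >= win_hi:
                break
            target = sense if m.strand == gene.strand else anti
            if mode == "start":
                p = m.start if gene.strand == "+" else m.end - 1
                if win_lo <= p < win_hi:
                    o = gene.to_offset(p, a)
                    target[o + half_width] += 1
                continue
            lo, hi = max(m.start, win_lo), min(m.end, win_hi)
            o1 = gene.to_offset(lo, a)
            o2 = gene.to_offset(hi - 1, a)
            if o2 < o1:
                o1, o2 = o2, o1
            target[o1 + half_width : o2 + half_width + 1] += 1
    if n_regions == 0:
        raise ValueError(f"no gene provides anchor {anchor_kind!r}")
    return PositionalProfile(
        anchor_kind=anchor_kind,
        half_width=half_width,
        counts_sense=sense,
        counts_antisense=anti,
        n_regions=n_regions,
    )


def moving_average(values, window: int):
    """Centred moving mean with a shrinking window at the array edges.

    ``window`` must be odd; 1 is the identity. Accepts a 1-D array or a
    :class:`PositionalProfile` (each strand tally smoothed independently,
    returned as a new profile with float counts).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive integer")
    if isinstance(values, PositionalProfile):
        return replace(
            values,
            counts_sense=moving_average(values.counts_sense, window),
            counts_antisense=moving_average(values.counts_antisense, window),
        )
    x = np.asarray(values, dtype=float)
    if window > x.size:
        raise ValueError("window exceeds profile length")
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / norm


# ---------------------------------------------------------------------------
# densities


def region_union_span(regions: list[tuple[str, int, int]]) -> int:
    """Total bp covered by a region set, overlaps counted once."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def count_overlapping(motifs: list[G4Motif], regions: list[tuple[str, int, int]]) -> int:
    """Motifs overlapping any region by >= 1 bp, each motif counted once."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    # merge regions, then binary-search each motif
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    n = 0
    for m in motifs:
        if m.chrom not in merged:
            continue
        starts, ends = merged[m.chrom]
        i = np.searchsorted(starts, m.end, side="left") - 1
        if i >= 0 and ends[i] > m.start:
            n += 1
    return n


def density(
    motifs: list[G4Motif], regions: list[tuple[str, int, int]], feature_class: str
) -> dict:
    """One density-report row: motif count and motifs/Mb over a region set."""
    if not regions:
        raise ValueError("density requires a non-empty region set")
    span = region_union_span(regions)
    if span == 0:
        raise ValueError("region set has zero span")
    n = count_overlapping(motifs, regions)
    return {
        "feature_class": feature_class,
        "n_motifs": n,
        "span_bp": span,
        "density_per_Mb": n / span * 1e6,
    }


def density_report(
    motifs: list[G4Motif], region_sets: dict[str, list[tuple[str, int, int]]]
) -> pd.DataFrame:
    """Density rows for several feature classes as a DataFrame."""
    return pd.DataFrame([density(motifs, r, c) for c, r in region_sets.items()])


# ---------------------------------------------------------------------------
# peak gene sets and genome bins


def _zone_interval(gene: GeneModel, anchor: int, zone: tuple[int, int]) -> tuple[int, int]:
    """Genomic interval of a gene-oriented offset zone [o1, o2)."""
    o1, o2 = zone
    if gene.strand == "+":
        return anchor + o1, anchor + o2
    return anchor - o2 + 1, anchor - o1 + 1


def peak_gene_sets(
    motifs: list[G4Motif], genes: list[GeneModel]
) -> dict[str, set[str]]:
    """Genes with a gene-antisense motif in peak1 / peak2 / peak3.

    peak1 = [-250, 0) and peak2 = [0, +250) around the start codon; peak3 =
    the first 100 bp of intron 1 (multi-exon genes only). Sets may intersect.
    """
    by_chrom: dict[str, list[G4Motif]] = {}
    for m in motifs:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: dict[str, set[str]] = {"peak1": set(), "peak2": set(), "peak3": set()}
    for gene in genes:
        ms = [m for m in by_chrom.get(gene.chrom, ()) if m.strand != gene.strand]
        if not ms or not gene.has_cds:
            continue
        a = gene.start_codon_pos()
        zones = [
            ("peak1", _zone_interval(gene, a, PEAK1_ZONE)),
            ("peak2", _zone_interval(gene, a, PEAK2_ZONE)),
        ]
        if gene.n_exons >= 2:
            i1 = gene.intron1_start_pos()
            zones.append(("peak3", _zone_interval(gene, i1, (0, PEAK3_LEN))))
        for name, (zs, ze) in zones:
            if any(m.start < ze and m.end > zs for m in ms):
                out[name].add(gene.gene_id)
    return out


def bin_genome(
    chrom_lengths: dict[str, int],
    features: list[tuple[str, int]],
    n_bins: int = 1000,
) -> pd.DataFrame:
    """Fixed-count per-chromosome histogram (Circos track input).

    Each chromosome is split into ``n_bins`` equal-width bins (the last bin
    absorbs the remainder); every feature is binned by its start coordinate.
    ``features`` is a list of (chrom, start).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rows = []
    index: dict[str, int] = {}
    for chrom, length in chrom_lengths.items():
        width = max(length // n_bins, 1)
        nb = min(n_bins, length)
        index[chrom] = len(rows)
        for b in range(nb):
            end = length if b == nb - 1 else (b + 1) * width
            rows.append([chrom, b * width, end, 0])
    for chrom, start in features:
        if chrom not in index:
            continue
        length = chrom_lengths[chrom]
        width = max(length // n_bins, 1)
        nb = min(n_bins, length)
        b = min(start // width, nb - 1)
        rows[index[chrom] + b][3] += 1
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "count"])
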