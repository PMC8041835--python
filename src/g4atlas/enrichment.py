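"""Shuffle-based genomic enrichment and GO-term association tests.

Fold enrichment of motifs in a region set is the observed motif overlap
divided by the overlap with length-preserving random placements of the same
intervals across the genome (bedtools-shuffle style: chromosome chosen with
probability proportional to its length, start uniform in the valid range,
shuffled intervals free to overlap each other). A fold of 1 is the null.

GO association uses a Pearson chi-square on the 2x2 table (G4-gene x term)
per GO term, without continuity correction by default, and GO
over-representation uses the hypergeometric upper tail; both are corrected
with Benjamini-Hochberg FDR. Terms are tested exactly as annotated (no
ancestor propagation up the ontology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import G4Motif, SequenceRecord
from .profiles import count_overlapping


@dataclass
class ShuffleResult:
    seed: int | None
    n_intervals: int
    n_reps: int
    observed_overlap: int
    shuffled_overlap: float
    shuffled_overlaps: list[int]
    fold: float


def shuffle_intervals(
    regions: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    seed: int | None = None,
    n_reps: int = 1,
    rng: np.random.Generator | None = None,
) -> list[list[tuple[str, int, int]]]:
    """Length-preserving uniform random placement of a region set.

    Returns ``n_reps`` independent shuffled region sets. Each interval keeps
    its length and lands on a chromosome drawn with probability proportional
    to chromosome length (among chromosomes it fits on), start uniform.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    max_len = int(lengths.max()) if len(chroms) else 0
    out = []
    for _ in range(n_reps):
        rep = []
        for chrom, s, e in regions:
            size = e - s
            if size > max_len:
                raise ValueError(f"region of {size} bp fits on no chromosome")
            ok = lengths >= size
            p = lengths * ok
            p /= p.sum()
            ci = rng.choice(len(chroms), p=p)
            start = int(rng.integers(0, chrom_lengths[chroms[ci]] - size + 1))
            rep.append((chroms[ci], start, start + size))
        out.append(rep)
    return out


def fold_enrichment(
    motifs: list[G4Motif],
    regions: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    seed: int | None = None,
    n_reps: int = 1,
) -> ShuffleResult:
    """Observed / shuffled motif overlap of a region set.

    ``shuffled_overlap`` is averaged over ``n_reps`` shuffles. Because the
    shuffle preserves every interval length, the count ratio and the
    density (per-Mb) ratio coincide.
    """
    observed = count_overlapping(motifs, regions)
    reps = shuffle_intervals(regions, chrom_lengths, seed=seed, n_reps=n_reps)
    counts = [count_overlapping(motifs, rep) for rep in reps]
    mean_shuffled = float(np.mean(counts))
    if mean_shuffled == 0:
        raise ValueError(
            "shuffled overlap is zero; increase n_reps or check the inputs"
        )
    return ShuffleResult(
        seed=seed,
        n_intervals=len(regions),
        n_reps=n_reps,
        observed_overlap=observed,
        shuffled_overlap=mean_shuffled,
        shuffled_overlaps=counts,
        fold=observed / mean_shuffled,
    )


def random_background_density(
    scan_fn,
    total_bp: int,
    seed: int | None = None,
    n_datasets: int = 3,
) -> tuple[float, list[float]]:
    """Median motif density (per Mb) over iid uniform A/C/G/T datasets.

    Generates ``n_datasets`` (default three) independent random sequences of
    ``total_bp`` with equal nucleotide probabilities, scans each with
    ``scan_fn(record) -> list of motifs`` and returns the median density
    together with all per-dataset densities for audit.
    """
    if total_bp < 100_000:
        raise ValueError("random background needs >= 100 kb per dataset")
    rng = np.random.default_rng(seed)
    densities = []
    for k in range(n_datasets):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=total_bp)])
        rec = SequenceRecord(f"random_{k}", seq)
        densities.append(len(scan_fn(rec)) / total_bp * 1e6)
    return float(np.median(densities)), densities


# ---------------------------------------------------------------------------
# GO tests


def chi_square_2x2(a: int, b: int, c: int, d: int, correction: bool = False):
    """Pearson chi-square on a 2x2 table; returns (statistic, p_value).

    Degenerate tables (a zero margin) carry no association: statistic 0, p 1.
    """
    if min(a + b, c + d, a + c, b + d) == 0:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=correction
    )
    return float(stat), float(p)


def go_chi_square(
    g4_genes: set[str],
    all_genes: set[str],
    go_map: dict[str, set[str]],
    correction: bool = False,
) -> pd.DataFrame:
    """Per-term 2x2 Pearson chi-square of G4-gene status vs term membership.

    Rows: term, a (G4 & term), b (G4 & not term), c (non-G4 & term),
    d (non-G4 & not term), statistic, p_value, q_value (BH across tested
    terms), low_expected (any expected cell < 5).
    """
    if not all_genes:
        raise ValueError("empty gene universe")
    if not g4_genes <= all_genes:
        raise ValueError("g4_genes must be a subset of all_genes")
    terms: dict[str, int] = {}
    term_in_g4: dict[str, int] = {}
    for gene in all_genes:
        for t in go_map.get(gene, ()):
            terms[t] = terms.get(t, 0) + 1
            if gene in g4_genes:
                term_in_g4[t] = term_in_g4.get(t, 0) + 1
    n_g4, n_all = len(g4_genes), len(all_genes)
    rows = []
    for t in sorted(terms):
        a = term_in_g4.get(t, 0)
        c = terms[t] - a
        b = n_g4 - a
        d = (n_all - n_g4) - c
        stat, p = chi_square_2x2(a, b, c, d, correction=correction)
        exp_min = min(
            (a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)
        ) / n_all
        rows.append((t, a, b, c, d, stat, p, exp_min < 5))
    df = pd.DataFrame(
        rows, columns=["term", "a", "b", "c", "d", "statistic", "p_value", "low_expected"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df


def go_hypergeometric(
    subset: set[str],
    universe: set[str],
    go_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of a gene subset.

    p = P(X >= k) where k genes of the subset carry the term, out of a
    universe of M genes of which n carry it. BH-corrected; ``enriched`` flags
    q <= alpha. Terms annotated to no universe gene are skipped with a
    warning column omitted (they cannot be tested).
    """
    if not subset <= universe:
        raise ValueError("subset must be contained in the universe")
    if not universe:
        raise ValueError("empty gene universe")
    M, N = len(universe), len(subset)
    term_total: dict[str, int] = {}
    term_sub: dict[str, int] = {}
    for gene in universe:
        for t in go_map.get(gene, ()):
            term_total[t] = term_total.get(t, 0) + 1
            if gene in subset:
                term_sub[t] = term_sub.get(t, 0) + 1
    rows = []
    for t in sorted(term_total):
        n = term_total[t]
        if n == 0:
            continue
        k = term_sub.get(t, 0)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((t, k, n, N, M, p))
    df = pd.DataFrame(
        rows, columns=["term", "k_subset", "n_term", "n_subset", "n_universe", "p_value"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["enriched"] = df["q_value"] <= alpha
    else:
        df["q_value"] = []
        df["enriched"] = []
    return df
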