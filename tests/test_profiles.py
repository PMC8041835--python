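"""Density, positional-frequency, smoothing, peak and binning tests."""

import numpy as np
import pytest
from scipy import stats

from g4atlas import (
    G4Motif,
    GeneModel,
    bin_genome,
    density,
    density_report,
    moving_average,
    peak_gene_sets,
    positional_frequency,
)


def _motif(chrom, start, end, strand="+"):
    return G4Motif(chrom, start, end, strand, "N" * (end - start), 4, "perfect")


def _gene(gene_id, strand, start, end, blocks=None, chrom="chr1"):
    blocks = blocks or [(start, end)]
    order = tuple(sorted(blocks, reverse=(strand == "-")))
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
        cds_blocks=order, exon_blocks=order,
    )


class TestDensity:
    def test_counts_per_mb_identity(self):
        motifs = [_motif("chr1", i * 1000, i * 1000 + 15) for i in range(77)]
        row = density(motifs, [("chr1", 0, 1_000_000)], "genome")
        assert row["n_motifs"] == 77
        assert row["density_per_Mb"] == pytest.approx(77.0)

    def test_zero_motifs(self):
        row = density([], [("chr1", 0, 1000)], "x")
        assert row["density_per_Mb"] == 0.0

    def test_region_overlaps_counted_once(self):
        motifs = [_motif("chr1", 100, 130)]
        row = density(motifs, [("chr1", 0, 120), ("chr1", 110, 200)], "x")
        assert row["n_motifs"] == 1 and row["span_bp"] == 200

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            density([], [], "x")

    def test_report_has_one_row_per_class(self):
        df = density_report([], {"a": [("chr1", 0, 10)], "b": [("chr1", 0, 20)]})
        assert list(df["feature_class"]) == ["a", "b"]


class TestPositionalFrequency:
    def test_coverage_offsets_for_plus_gene(self):
        gene = _gene("g", "+", 5000, 6000)
        prof = positional_frequency([_motif("chr1", 4750, 4765)], [gene], "start_codon")
        nz = prof.offsets[prof.counts_sense > 0]
        assert nz.min() == -250 and nz.max() == -236
        assert prof.counts_antisense.sum() == 0
        assert prof.n_regions == 1

    def test_minus_gene_profile_mirrors(self):
        gp = _gene("gp", "+", 5000, 6000)
        gm = _gene("gm", "-", 5000, 6000)
        mp = _motif("chr1", 4750, 4765, "+")
        # mirrored position for the minus gene: anchor 5999, offsets -250..-236
        mm = _motif("chr1", 6235, 6250, "-")
        prof_p = positional_frequency([mp], [gp], "start_codon")
        prof_m = positional_frequency([mm], [gm], "start_codon")
        assert np.array_equal(prof_p.counts_sense, prof_m.counts_sense)

    def test_counts_both_is_sum_of_strands(self):
        gene = _gene("g", "+", 5000, 6000)
        motifs = [_motif("chr1", 4900, 4915, "+"), _motif("chr1", 5100, 5115, "-")]
        prof = positional_frequency(motifs, [gene], "start_codon")
        assert np.array_equal(prof.counts_both, prof.counts_sense + prof.counts_antisense)

    def test_start_mode_single_increment(self):
        gene = _gene("g", "+", 5000, 6000)
        prof = positional_frequency(
            [_motif("chr1", 4750, 4765)], [gene], "start_codon", mode="start"
        )
        assert prof.counts_sense.sum() == 1
        assert prof.offsets[prof.counts_sense > 0][0] == -250

    def test_no_anchored_genes_rejected(self):
        g = GeneModel("g", "chr1", "+", 0, 100)  # no CDS
        with pytest.raises(ValueError):
            positional_frequency([], [g], "start_codon")

    def test_per_mb_is_fraction_times_1e6(self):
        gene = _gene("g", "+", 5000, 6000)
        prof = positional_frequency([_motif("chr1", 4750, 4765)], [gene], "start_codon")
        assert np.allclose(
            prof.frequency("sense", "per_Mb"), prof.frequency("sense", "fraction") * 1e6
        )


class TestMovingAverage:
    def test_constant_profile_unchanged(self):
        x = np.full(500, 3.0)
        for w in (1, 99, 199):
            assert np.allclose(moving_average(x, w), x)

    def test_window_one_is_identity(self):
        x = np.arange(50, dtype=float)
        assert np.array_equal(moving_average(x, 1), x)

    def test_impulse_spreads_to_window(self):
        x = np.zeros(501)
        x[250] = 1.0
        sm = moving_average(x, 99)
        inside = (np.arange(501) >= 201) & (np.arange(501) <= 299)
        assert np.allclose(sm[inside], 1 / 99)
        assert np.allclose(sm[~inside], 0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 4)

    def test_two_impulses_merge_only_under_wide_window(self):
        """A 999-bp window fuses peaks 375 bp apart; a 99-bp window keeps them."""
        from scipy.signal import find_peaks

        x = np.zeros(10_000)
        x[4750] = 1.0  # offset -250 from centre
        x[5125] = 1.0  # offset +125
        for w, expect in ((999, 1), (99, 2)):
            sm = moving_average(x, w)
            peaks, _ = find_peaks(sm, height=0.5 * sm.max(), prominence=0.25 * sm.max())
            assert len(peaks) == expect

    def test_local_maxima_non_increasing_with_window(self, rng):
        x = rng.random(2001)
        def n_maxima(v):
            return int(np.sum((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])))
        counts = [n_maxima(moving_average(x, w)) for w in (1, 99, 199, 999)]
        assert counts == sorted(counts, reverse=True)


class TestPeakGeneSets:
    def test_antisense_motif_in_peak1_only(self):
        gene = _gene("g", "+", 5000, 6000)
        peaks = peak_gene_sets([_motif("chr1", 4900, 4920, "-")], [gene])
        assert peaks == {"peak1": {"g"}, "peak2": set(), "peak3": set()}

    def test_sense_motifs_never_count(self):
        gene = _gene("g", "+", 5000, 6000)
        peaks = peak_gene_sets([_motif("chr1", 4900, 4920, "+")], [gene])
        assert peaks["peak1"] == set()

    def test_single_exon_gene_never_in_peak3(self):
        gene = _gene("g", "+", 5000, 6000)  # one exon
        peaks = peak_gene_sets([_motif("chr1", 5000, 6000, "-")], [gene])
        assert peaks["peak3"] == set()

    def test_peak3_is_first_100bp_of_intron1(self):
        gene = _gene("g", "+", 5000, 7000, blocks=[(5000, 5400), (6000, 7000)])
        inside = _motif("chr1", 5450, 5465, "-")
        outside = _motif("chr1", 5520, 5535, "-")
        assert peak_gene_sets([inside], [gene])["peak3"] == {"g"}
        assert peak_gene_sets([outside], [gene])["peak3"] == set()

    def test_minus_gene_zones_mirror(self):
        gene = _gene("g", "-", 5000, 6000)
        # anchor 5999; peak1 genomic [6000, 6250), peak2 [5750, 6000)
        assert peak_gene_sets([_motif("chr1", 6100, 6115, "+")], [gene])["peak1"] == {"g"}
        assert peak_gene_sets([_motif("chr1", 5800, 5815, "+")], [gene])["peak2"] == {"g"}


class TestBinGenome:
    def test_feature_lands_in_first_bin(self):
        df = bin_genome({"chr1": 1000}, [("chr1", 5)], n_bins=10)
        assert df.iloc[0]["count"] == 1 and df["count"].sum() == 1
        assert (df.iloc[0]["bin_start"], df.iloc[0]["bin_end"]) == (0, 100)

    def test_counts_conserved(self, rng):
        feats = [("chr1", int(p)) for p in rng.integers(0, 100_000, size=500)]
        df = bin_genome({"chr1": 100_000}, feats, n_bins=97)
        assert df["count"].sum() == 500
        assert len(df) == 97
        assert df.iloc[-1]["bin_end"] == 100_000

    def test_uniform_features_pass_chi_square(self):
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(5):
            feats = [("chr1", int(p)) for p in rng.integers(0, 100_000, size=2000)]
            df = bin_genome({"chr1": 100_000}, feats, n_bins=50)
            pvals.append(stats.chisquare(df["count"]).pvalue)
        assert min(pvals) > 0.01
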