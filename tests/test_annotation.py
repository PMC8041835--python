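"""Annotation readers, motif-feature assignment and SNP classification."""

import numpy as np
import pytest

from g4atlas import (
    G4Motif,
    GeneModel,
    SNPRecord,
    assign_motifs,
    classify_snp_disruption,
    genes_with_g4,
    overlap_tes,
    read_genes,
    read_go_map,
    read_snps,
    read_te_intervals,
    snps_in_motifs,
)
from g4atlas.simulate import SyntheticSpec, MotifPlacement, generate

from oracles import naive_overlap_categories

MINIMAL = "GGGAGGGTGGGAGGG"


def _motif(chrom, start, end, strand="+", cls="perfect"):
    return G4Motif(chrom, start, end, strand, "N" * (end - start), 4, cls)


@pytest.fixture
def plus_gene():
    # two exons: [1000,1400) and [1800,2200), CDS == exons
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        start=1000,
        end=2200,
        cds_blocks=((1000, 1400), (1800, 2200)),
        exon_blocks=((1000, 1400), (1800, 2200)),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="g2",
        chrom="chr1",
        strand="-",
        start=5000,
        end=6200,
        cds_blocks=((5800, 6200), (5000, 5400)),
        exon_blocks=((5800, 6200), (5000, 5400)),
    )


class TestReaders:
    def test_gff3_coordinates_convert_to_half_open(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t300\t.\t+\t.\tID=gA\n"
            "chr1\tx\tmRNA\t1\t300\t.\t+\t.\tID=gA.1;Parent=gA\n"
            "chr1\tx\texon\t1\t300\t.\t+\t.\tParent=gA.1\n"
            "chr1\tx\tCDS\t1\t300\t.\t+\t0\tParent=gA.1\n"
        )
        (g,) = read_genes(p)
        assert (g.start, g.end) == (0, 300)
        assert g.cds_blocks == ((0, 300),)

    def test_minus_strand_blocks_in_transcription_order(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t101\t900\t.\t-\t.\tID=gB\n"
            "chr1\tx\tmRNA\t101\t900\t.\t-\t.\tID=gB.1;Parent=gB\n"
            "chr1\tx\texon\t101\t300\t.\t-\t.\tParent=gB.1\n"
            "chr1\tx\texon\t601\t900\t.\t-\t.\tParent=gB.1\n"
            "chr1\tx\tCDS\t101\t300\t.\t-\t0\tParent=gB.1\n"
            "chr1\tx\tCDS\t601\t900\t.\t-\t0\tParent=gB.1\n"
        )
        (g,) = read_genes(p)
        assert g.cds_blocks == ((600, 900), (100, 300))
        assert g.start_codon_pos() == 899
        assert g.intron1_start_pos() == 599

    def test_synthetic_gff3_round_trip_equals_truth(self, tmp_path):
        spec = SyntheticSpec(
            chrom_lengths=(120_000,), n_genes=8, seed=5, te_density=0.0,
            snp_plan=(), scrub_classes=("perfect",),
        )
        ds = generate(spec, out_dir=tmp_path)
        back = read_genes(tmp_path / "genes.gff3")
        want = {
            (g.gene_id, g.chrom, g.strand, g.start, g.end, g.cds_blocks, g.exon_blocks)
            for g in ds.truth.genes
        }
        got = {
            (g.gene_id, g.chrom, g.strand, g.start, g.end, g.cds_blocks, g.exon_blocks)
            for g in back
        }
        assert got == want

    def test_te_reader_bed_and_gff(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t10\t50\tRLX\n")
        assert read_te_intervals(bed) == [("chr1", 10, 50, "RLX")]
        gff = tmp_path / "t.gff3"
        gff.write_text("chr1\tx\tRLG_gypsy\t11\t50\t.\t+\t.\tID=te1\n")
        assert read_te_intervals(gff) == [("chr1", 10, 50, "RLG_gypsy")]

    def test_snp_reader_converts_and_validates(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("marker_id\tchrom\tpos\tref\talt\nm1\tchr1\t5\tG\tA\n")
        (s,) = read_snps(p)
        assert (s.pos, s.ref_allele, s.alt_allele) == (4, "G", "A")
        with pytest.raises(ValueError, match="does not match"):
            read_snps(p, genome={"chr1": "AAAAAAAAAA"})

    def test_go_map_reader(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("g1\tGO:0000001,GO:0000002\ng2\tGO:0000002\n")
        go = read_go_map(p)
        assert go == {"g1": {"GO:0000001", "GO:0000002"}, "g2": {"GO:0000002"}}


class TestAssignMotifs:
    def test_upstream_flank_categories(self, plus_gene):
        (fa,) = assign_motifs([_motif("chr1", 940, 960)], [plus_gene])
        assert fa.categories == {"upstream_1k", "flank5_500"}

    def test_second_cds_block_is_cds_rest(self, plus_gene):
        (fa,) = assign_motifs([_motif("chr1", 1900, 1920)], [plus_gene])
        assert fa.categories == {"gene_body", "cds_rest"}

    def test_first_cds_wins_over_rest(self, plus_gene):
        # spans the first intron boundary into CDS 1
        (fa,) = assign_motifs([_motif("chr1", 1390, 1420)], [plus_gene])
        assert "cds_first" in fa.categories and "cds_rest" not in fa.categories
        assert "intron_first" in fa.categories

    def test_minus_gene_upstream_is_right_of_gene(self, minus_gene):
        (fa,) = assign_motifs([_motif("chr1", 6300, 6320)], [minus_gene])
        assert fa.categories == {"upstream_1k", "flank5_500"}
        (fa2,) = assign_motifs([_motif("chr1", 4600, 4620)], [minus_gene])
        assert fa2.categories == {"downstream_1k", "flank3_500"}

    def test_agrees_with_naive_all_pairs_check(self, plus_gene, minus_gene, rng):
        genes = [plus_gene, minus_gene]
        motifs = [
            _motif("chr1", int(s), int(s) + int(rng.integers(10, 40)))
            for s in rng.integers(0, 7500, size=300)
        ]
        assignments = assign_motifs(motifs, genes)
        for m, fa in zip(motifs, assignments):
            want = set()
            for g in genes:
                want |= naive_overlap_categories(m, g)
            assert fa.categories == want, (m.start, m.end)

    def test_gene_flag_monotone_in_flank(self, plus_gene, minus_gene, rng):
        genes = [plus_gene, minus_gene]
        motifs = [_motif("chr1", int(s), int(s) + 15) for s in rng.integers(0, 8000, 200)]
        sizes = [0, 100, 500, 1000, 2000]
        counts = [len(genes_with_g4(motifs, genes, flank=f)) for f in sizes]
        assert counts == sorted(counts)


class TestTEsAndSNPs:
    def test_no_tes_gives_zero(self):
        assert overlap_tes([_motif("chr1", 0, 15)], []) == (0, 0.0, {})

    def test_nested_tes_count_motif_once(self):
        tes = [("chr1", 0, 100, "RLX"), ("chr1", 0, 100, "RLX"), ("chr1", 10, 40, "RLC_copia")]
        n, frac, fams = overlap_tes([_motif("chr1", 10, 25)], tes)
        assert (n, frac) == (1, 1.0)
        assert fams == {"RLX": 1, "RLC_copia": 1}

    def test_snp_interval_boundaries_half_open(self):
        m = _motif("chr1", 100, 115)
        inside = SNPRecord("a", "chr1", 100, "G", "A")
        outside = SNPRecord("b", "chr1", 115, "G", "A")
        rows = snps_in_motifs([m], [inside, outside])
        assert [(r[0].marker_id, r[2]) for r in rows] == [("a", 0)]


class TestSNPDisruption:
    def test_stem_hit_without_rescue_is_disruptive(self):
        genome = {"chr1": "TTTT" + MINIMAL + "TTTT"}
        (m,) = _scan(genome)
        snp = SNPRecord("s", "chr1", 4 + 5, "G", "A")  # middle G of stem 2
        assert classify_snp_disruption(m, snp, genome) == "stem_disruptive"

    def test_redundant_run_slides_and_tolerates(self):
        genome = {"chr1": "TTTT" + "G" + MINIMAL + "TTTT"}  # first run has 4 Gs
        (m,) = _scan(genome)
        snp = SNPRecord("s", "chr1", 4, "G", "A")  # first G of the long run
        assert classify_snp_disruption(m, snp, genome) == "stem_tolerated"

    def test_loop_position_is_loop_or_flank(self):
        genome = {"chr1": "TTTT" + MINIMAL + "TTTT"}
        (m,) = _scan(genome)
        snp = SNPRecord("s", "chr1", 4 + 3, "A", "C")
        assert classify_snp_disruption(m, snp, genome) == "loop_or_flank"

    def test_flank_position_is_loop_or_flank(self):
        genome = {"chr1": "TTTT" + MINIMAL + "TTTT"}
        (m,) = _scan(genome)
        snp = SNPRecord("s", "chr1", 2, "T", "C")
        assert classify_snp_disruption(m, snp, genome) == "loop_or_flank"

    def test_minus_strand_motif_classifies_symmetrically(self):
        from g4atlas import revcomp

        genome = {"chr1": "TTTT" + revcomp(MINIMAL) + "TTTT"}
        from g4atlas import scan_both_strands, SequenceRecord

        (m,) = scan_both_strands(SequenceRecord("chr1", genome["chr1"]))
        assert m.strand == "-"
        # middle C of the C-run mirroring stem 2
        pos = m.end - 1 - 5
        snp = SNPRecord("s", "chr1", pos, genome["chr1"][pos], "T")
        assert classify_snp_disruption(m, snp, genome) == "stem_disruptive"

    def test_identical_alleles_never_disruptive(self):
        genome = {"chr1": "TTTT" + MINIMAL + "TTTT"}
        (m,) = _scan(genome)
        for off in range(15):
            ref = MINIMAL[off]
            snp = SNPRecord("s", "chr1", 4 + off, ref, ref)
            assert classify_snp_disruption(m, snp, genome) != "stem_disruptive"

    def test_snp_outside_flank_rejected(self):
        genome = {"chr1": "T" * 40 + MINIMAL + "T" * 40}
        (m,) = _scan(genome)
        with pytest.raises(ValueError, match="flank"):
            classify_snp_disruption(m, SNPRecord("s", "chr1", 5, "T", "A"), genome)


def _scan(genome):
    from g4atlas import SequenceRecord, scan_perfect

    (chrom, seq), = genome.items()
    return scan_perfect(SequenceRecord(chrom, seq))


def test_first_cds_concentration_matches_planted_share(rng):
    """Planting 80% of CDS motifs in first CDS blocks is recovered within 3%."""
    genes, motifs = [], []
    pos = 2000
    for i in range(1000):
        blocks = ((pos, pos + 400), (pos + 900, pos + 1300))
        genes.append(
            GeneModel(
                gene_id=f"g{i}", chrom="chr1", strand="+", start=pos, end=pos + 1300,
                cds_blocks=blocks, exon_blocks=blocks,
            )
        )
        target = blocks[0] if rng.random() < 0.8 else blocks[1]
        s = int(rng.integers(target[0], target[1] - 15))
        motifs.append(_motif("chr1", s, s + 15))
        pos += 4000
    assignments = assign_motifs(motifs, genes)
    n_first = sum("cds_first" in fa.categories for fa in assignments)
    n_cds = sum(
        bool({"cds_first", "cds_rest"} & fa.categories) for fa in assignments
    )
    assert n_cds == 1000
    assert abs(n_first / n_cds - 0.8) <= 0.03
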