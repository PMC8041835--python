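"""Seeded synthetic genomes with planted motifs, genes, TEs and SNPs.

The generator emulates the data shape the distribution analyses assume: a
multi-chromosome FASTA with a controlled GC background, non-overlapping
gene models (multi- and single-exon, CDS == exons, no UTRs — like many
plant annotations), G4 motifs of every class planted at configured
gene-relative offsets and strands, TE intervals, SNPs in chosen zones, and
a GO map. Everything is recorded in a machine-readable truth ledger so
recovery tests can be exact.

The random background is *scrubbed*: any spurious perfect (and, by default,
imperfect) motif on either strand is broken by mutating one guanine
(cytosine on the antisense pattern) in a central stem, iterating to a
fixpoint, so that after planting, the only motifs in the genome are the
planted ones. Planted motifs are written with short non-G/non-C buffer
sequence on both sides so they can neither extend nor merge with the
background, making coordinate recovery exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import GeneModel, SNPRecord
from .imperfect import ImperfectParams, _scan_strand
from .records import SequenceRecord, revcomp
from .scan import _pattern

# minimal planted sequence per motif class (exact zone arithmetic)
PLANT_SEQS = {
    "perfect": "GGGAGGGTGGGAGGG",  # 15 bp, 4 stems
    "multimeric": "GGGA" * 7 + "GGG",  # 31 bp, 8 stems
    "imperfect": "GGAGGTGGGTGGGTGGG",  # 17 bp, bulged first stem
    "imperfect_long": "GGAGG" + "T" * 9 + "GGG" + "T" + "GGG" + "T" + "GGG",
}

BUFFER = "ATATATAT"  # 8 bp: longer than any loop, free of G and C

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MotifPlacement:
    """One planting rule.

    zone: 'offset' plants at ``offset`` (gene-oriented 5' start relative to
    the start codon); 'peak1'/'peak2'/'peak3' are shorthands for the three
    antisense enrichment zones; 'uniform' scatters motifs anywhere on the
    genome; 'gene_body' scatters them inside gene bodies. ``probability``
    plants per-gene Bernoulli; ``count`` plants an exact number (sampling
    genes without replacement for gene zones).
    """

    motif_class: str = "perfect"
    zone: str = "offset"
    offset: int = 0
    relation: str = "antisense"  # sense | antisense; for 'uniform': + | -
    probability: float | None = None
    count: int | None = None

    def __post_init__(self) -> None:
        if self.motif_class not in PLANT_SEQS:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if (self.probability is None) == (self.count is None):
            raise ValueError("give exactly one of probability / count")


# the peak enrichment zones, as gene-oriented offsets of the motif 5' start
_ZONE_OFFSETS = {"peak1": -250, "peak2": 125}
_PEAK3_INTRON_OFFSET = 5


#: default planting: antisense perfect motifs at the three peak zones, with
#: per-gene probabilities 0.6 / 0.3 / 0.1 (upstream-biased, as in real genomes)
DEFAULT_PLACEMENTS = (
    MotifPlacement(zone="peak1", probability=0.6),
    MotifPlacement(zone="peak2", probability=0.3),
    MotifPlacement(zone="peak3", probability=0.1),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic genome."""

    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    gc_content: float = 0.44
    n_genes: int = 500
    multi_exon_fraction: float = 0.69
    motif_placements: tuple[MotifPlacement, ...] = DEFAULT_PLACEMENTS
    te_density: float = 0.3
    snp_plan: tuple[tuple[str, int], ...] = (
        ("stem", 10),
        ("loop", 10),
        ("flank", 10),
        ("intergenic", 10),
    )
    n_go_terms: int = 30
    seed: int = 0
    scrub_classes: tuple[str, ...] = ("perfect", "imperfect")

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if not 0 <= self.multi_exon_fraction <= 1:
            raise ValueError("multi_exon_fraction must be in [0,1]")
        if not 0 <= self.te_density < 1:
            raise ValueError("te_density must be in [0,1)")
        if self.n_genes > 0 and min(self.chrom_lengths) < 30_000:
            raise ValueError("chromosomes must be >= 10x a mean gene length")


@dataclass(frozen=True)
class PlantedMotif:
    chrom: str
    start: int
    end: int
    strand: str
    motif_class: str
    host_gene: str | None
    zone: str


@dataclass(frozen=True)
class PlantedSNP:
    snp: SNPRecord
    zone: str
    motif_id: str | None


@dataclass
class SyntheticTruth:
    """Ledger of everything the generator planted."""

    motifs: list[PlantedMotif] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    tes: list[tuple[str, int, int, str]] = field(default_factory=list)
    snps: list[PlantedSNP] = field(default_factory=list)
    go_map: dict[str, set[str]] = field(default_factory=dict)
    scrub_iterations: int = 0


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genome: dict[str, str]
    truth: SyntheticTruth

    @property
    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(c, s) for c, s in self.genome.items()]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write FASTA/GFF3/BED/TSV outputs plus the truth tables."""
        return _write_dataset(self, Path(out_dir))


# ---------------------------------------------------------------------------
# background and scrubbing


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _spurious_intervals(seq: str, classes: tuple[str, ...]) -> list[tuple[int, int, str]]:
    out = []
    for base in "GC":
        if "perfect" in classes:
            out.extend((m.start(), m.end(), base) for m in _pattern(base, 4).finditer(seq))
        for cls, params in (
            ("imperfect", ImperfectParams()),
            ("imperfect_long", ImperfectParams(max_loop=12)),
        ):
            if cls in classes:
                ivs = sorted((s, e) for s, e, _ in _scan_strand(seq, params, base))
                merged: list[list[int]] = []
                for s, e in ivs:
                    if merged and s <= merged[-1][1]:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([s, e])
                out.extend((s, e, base) for s, e in merged)
    return out


def _break_interval(arr: np.ndarray, s: int, e: int, base: str) -> None:
    """Mutate the middle base of the middle run of ``base`` in [s, e)."""
    code = ord(base)
    runs = []
    i = s
    while i < e:
        if arr[i] == code:
            j = i
            while j < e and arr[j] == code:
                j += 1
            if j - i >= 2:
                runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:  # lone bases only; break the first one
        for i in range(s, e):
            if arr[i] == code:
                runs = [(i, i + 1)]
                break
    rs, re_ = runs[len(runs) // 2]
    arr[(rs + re_) // 2] = ord("T") if base == "G" else ord("A")


MAX_SCRUB_ITERATIONS = 10


def scrub(arrays: dict[str, np.ndarray], classes: tuple[str, ...]) -> int:
    """Break every spurious motif, iterating to a fixpoint. Returns #iterations."""
    if not classes:
        return 0
    for it in range(1, MAX_SCRUB_ITERATIONS + 1):
        dirty = False
        for arr in arrays.values():
            seq = arr.tobytes().decode("ascii")
            ivs = _spurious_intervals(seq, classes)
            if ivs:
                dirty = True
                for s, e, base in ivs:
                    _break_interval(arr, s, e, base)
        if not dirty:
            return it - 1
    raise RuntimeError(
        f"background scrub did not converge within {MAX_SCRUB_ITERATIONS} iterations"
    )


# ---------------------------------------------------------------------------
# gene models


def _make_genes(spec: SyntheticSpec, rng: np.random.Generator) -> list[GeneModel]:
    total = sum(spec.chrom_lengths)
    per_chrom = [round(spec.n_genes * L / total) for L in spec.chrom_lengths]
    # fix rounding drift
    while sum(per_chrom) > spec.n_genes:
        per_chrom[int(np.argmax(per_chrom))] -= 1
    while sum(per_chrom) < spec.n_genes:
        per_chrom[int(np.argmin(per_chrom))] += 1
    genes = []
    gid = 0
    for ci, (L, n_c) in enumerate(zip(spec.chrom_lengths, per_chrom)):
        if n_c == 0:
            continue
        chrom = f"chr{ci + 1}"
        spacing = L // n_c
        for k in range(n_c):
            n_exons = 1
            if rng.random() < spec.multi_exon_fraction:
                n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(300, 601, size=n_exons)
            intron_lens = rng.integers(300, 801, size=max(n_exons - 1, 0))
            span = int(exon_lens.sum() + intron_lens.sum())
            margin = 1300  # room for 1 kb flanks plus planted-motif buffers
            if spacing < span + 2 * margin:
                raise ValueError(
                    "infeasible packing: too many genes for the genome size"
                )
            jitter = int(rng.integers(0, spacing - span - 2 * margin + 1))
            start = k * spacing + margin + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            blocks = []
            pos = start
            for x, ln in enumerate(exon_lens):
                blocks.append((pos, pos + int(ln)))
                if x < n_exons - 1:
                    pos += int(ln) + int(intron_lens[x])
            end = blocks[-1][1]
            order = blocks if strand == "+" else blocks[::-1]
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    cds_blocks=tuple(order),
                    exon_blocks=tuple(order),
                    confidence="HC",
                )
            )
    return genes


# ---------------------------------------------------------------------------
# planting


def _plant_interval(gene: GeneModel, anchor: int, offset: int, length: int) -> tuple[int, int]:
    """Genomic [start, end) of a motif whose gene-oriented 5' start is ``offset``."""
    if gene.strand == "+":
        return anchor + offset, anchor + offset + length
    return anchor - offset - length + 1, anchor - offset + 1


def _write_motif(
    arrays: dict[str, np.ndarray],
    occupied: dict[str, list[tuple[int, int]]],
    chrom: str,
    start: int,
    strand: str,
    motif_class: str,
) -> tuple[int, int]:
    seq = PLANT_SEQS[motif_class]
    fwd = seq if strand == "+" else revcomp(seq)
    payload = BUFFER + fwd + BUFFER
    lo = start - len(BUFFER)
    hi = lo + len(payload)
    arr = arrays[chrom]
    if lo < 0 or hi > arr.size:
        raise ValueError(f"planted motif out of bounds on {chrom}: [{lo},{hi})")
    for s, e in occupied[chrom]:
        if lo < e and hi > s:
            raise ValueError(
                f"planted motif collision on {chrom} at [{lo},{hi}) vs [{s},{e})"
            )
    arr[lo:hi] = np.frombuffer(payload.encode("ascii"), dtype=np.uint8)
    occupied[chrom].append((lo, hi))
    return start, start + len(seq)


def _plant_motifs(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    arrays: dict[str, np.ndarray],
    genes: list[GeneModel],
) -> list[PlantedMotif]:
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in arrays}
    planted: list[PlantedMotif] = []
    chroms = list(arrays)
    lengths = np.array([arrays[c].size for c in chroms], dtype=float)
    for rule in spec.motif_placements:
        length = len(PLANT_SEQS[rule.motif_class])
        if rule.zone in ("offset", "peak1", "peak2", "peak3"):
            hosts = genes
            if rule.zone == "peak3":
                hosts = [g for g in genes if g.n_exons >= 2]
                if not hosts:
                    raise ValueError("peak3 planting requires multi-exon genes")
            if rule.probability is not None:
                chosen = [g for g in hosts if rng.random() < rule.probability]
            else:
                if rule.count > len(hosts):
                    raise ValueError("not enough genes for requested count")
                idx = rng.choice(len(hosts), size=rule.count, replace=False)
                chosen = [hosts[i] for i in sorted(idx)]
            for g in chosen:
                if rule.zone == "peak3":
                    anchor = g.intron1_start_pos()
                    offset = _PEAK3_INTRON_OFFSET
                else:
                    anchor = g.start_codon_pos()
                    offset = _ZONE_OFFSETS.get(rule.zone, rule.offset)
                s, _e = _plant_interval(g, anchor, offset, length)
                strand = g.strand if rule.relation == "sense" else ("-" if g.strand == "+" else "+")
                ps, pe = _write_motif(arrays, occupied, g.chrom, s, strand, rule.motif_class)
                planted.append(
                    PlantedMotif(g.chrom, ps, pe, strand, rule.motif_class, g.gene_id, rule.zone)
                )
        elif rule.zone in ("uniform", "gene_body"):
            n = rule.count
            if n is None:
                n = int(rng.binomial(len(genes), rule.probability))
            strand_choice = rule.relation if rule.relation in ("+", "-") else None
            for _ in range(n):
                strand = strand_choice or ("+" if rng.random() < 0.5 else "-")
                for _try in range(200):
                    if rule.zone == "uniform":
                        ci = rng.choice(len(chroms), p=lengths / lengths.sum())
                        chrom = chroms[ci]
                        s = int(rng.integers(len(BUFFER), arrays[chrom].size - length - len(BUFFER)))
                    else:
                        g = genes[int(rng.integers(0, len(genes)))]
                        chrom = g.chrom
                        s = int(rng.integers(g.start, g.end - length))
                    lo, hi = s - len(BUFFER), s + length + len(BUFFER)
                    if all(lo >= e or hi <= b for b, e in occupied[chrom]):
                        break
                else:
                    raise ValueError("could not place uniform motif without collision")
                ps, pe = _write_motif(arrays, occupied, chrom, s, strand, rule.motif_class)
                planted.append(
                    PlantedMotif(chrom, ps, pe, strand, rule.motif_class, None, rule.zone)
                )
        else:
            raise ValueError(f"unknown placement zone {rule.zone!r}")
    return planted


# ---------------------------------------------------------------------------
# TEs, SNPs, GO


def _plant_tes(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    arrays: dict[str, np.ndarray],
    genes: list[GeneModel],
) -> list[tuple[str, int, int, str]]:
    if spec.te_density <= 0:
        return []
    families = ["RLX", "RLG_gypsy", "RLC_copia", "DTC_cacta", "other"]
    weights = np.array([0.30, 0.22, 0.20, 0.13, 0.15])
    weights /= weights.sum()
    tes = []
    for ci, chrom in enumerate(arrays):
        L = arrays[chrom].size
        blocked = sorted(
            (max(g.start - 1000, 0), min(g.end + 1000, L))
            for g in genes
            if g.chrom == chrom
        )
        gaps = []
        pos = 0
        for s, e in blocked:
            if s > pos:
                gaps.append((pos, s))
            pos = max(pos, e)
        if pos < L:
            gaps.append((pos, L))
        intergenic = sum(e - s for s, e in gaps)
        if intergenic == 0:
            continue
        fill = min(spec.te_density * L / intergenic, 0.95)
        for gs, ge in gaps:
            cur = gs
            while True:
                ln = int(rng.integers(500, 3001))
                skip = int(ln * (1 / fill - 1)) if fill < 1 else 0
                if cur + ln > ge:
                    break
                fam = families[int(rng.choice(len(families), p=weights))]
                tes.append((chrom, cur, cur + ln, fam))
                cur += ln + max(skip, 1)
    return tes


# SNP zone -> offset within the minimal perfect planted motif (5'->3')
_SNP_STEM_OFFSET = 5  # middle G of stem 2
_SNP_LOOP_OFFSET = 3  # first loop base


def _plant_snps(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    genome: dict[str, str],
    planted: list[PlantedMotif],
) -> list[PlantedSNP]:
    plan = dict(spec.snp_plan)
    perfect = [m for m in planted if m.motif_class == "perfect"]
    need = plan.get("stem", 0) + plan.get("loop", 0) + plan.get("flank", 0)
    if need > 0 and not perfect:
        raise ValueError("snp_plan needs planted perfect motifs")
    snps: list[PlantedSNP] = []
    k = 0

    def alt_for(ref: str) -> str:
        return next(b for b in "ACGT" if b != ref)

    cursor = 0
    for zone in ("stem", "loop", "flank"):
        for _ in range(plan.get(zone, 0)):
            m = perfect[cursor % len(perfect)]
            cursor += 1
            if zone == "flank":
                pos = m.start - 3  # inside the planted buffer
            else:
                off = _SNP_STEM_OFFSET if zone == "stem" else _SNP_LOOP_OFFSET
                pos = m.start + off if m.strand == "+" else m.end - 1 - off
            ref = genome[m.chrom][pos]
            k += 1
            snps.append(
                PlantedSNP(
                    SNPRecord(f"snp_{k:04d}", m.chrom, pos, ref, alt_for(ref)),
                    zone,
                    f"{m.motif_class}:{m.chrom}:{m.start}-{m.end}:{m.strand}",
                )
            )
    motif_spans: dict[str, list[tuple[int, int]]] = {}
    for m in planted:
        motif_spans.setdefault(m.chrom, []).append((m.start - 12, m.end + 12))
    chroms = list(genome)
    lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    for _ in range(plan.get("intergenic", 0)):
        for _try in range(200):
            ci = rng.choice(len(chroms), p=lens / lens.sum())
            chrom = chroms[ci]
            pos = int(rng.integers(0, len(genome[chrom])))
            if all(not (s <= pos < e) for s, e in motif_spans.get(chrom, ())):
                break
        else:
            raise ValueError("could not place intergenic SNP")
        ref = genome[chrom][pos]
        if ref == "N":
            continue
        k += 1
        snps.append(
            PlantedSNP(SNPRecord(f"snp_{k:04d}", chrom, pos, ref, alt_for(ref)), "intergenic", None)
        )
    return snps


def _make_go_map(
    spec: SyntheticSpec, rng: np.random.Generator, genes: list[GeneModel]
) -> dict[str, set[str]]:
    terms = [f"GO:{i + 1:07d}" for i in range(spec.n_go_terms)]
    prevalence = rng.uniform(0.05, 0.4, size=len(terms))
    go: dict[str, set[str]] = {}
    for g in genes:
        mask = rng.random(len(terms)) < prevalence
        go[g.gene_id] = {t for t, m in zip(terms, mask) if m}
    return go


# ---------------------------------------------------------------------------
# top level


def generate(spec: SyntheticSpec, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Build a synthetic genome per ``spec``; deterministic under its seed."""
    rng = np.random.default_rng(spec.seed)
    arrays = {
        f"chr{i + 1}": _random_background(rng, L, spec.gc_content)
        for i, L in enumerate(spec.chrom_lengths)
    }
    n_iter = scrub(arrays, spec.scrub_classes)
    genes = _make_genes(spec, rng)
    planted = _plant_motifs(spec, rng, arrays, genes)
    tes = _plant_tes(spec, rng, arrays, genes)
    genome = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}
    snps = _plant_snps(spec, rng, genome, planted)
    go = _make_go_map(spec, rng, genes)
    truth = SyntheticTruth(
        motifs=planted, genes=genes, tes=tes, snps=snps, go_map=go,
        scrub_iterations=n_iter,
    )
    ds = SyntheticDataset(spec=spec, genome=genome, truth=truth)
    if out_dir is not None:
        ds.write(out_dir)
    return ds


def plant_profile_cohort(
    n_genes: int = 500,
    probabilities: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000),
    motif_class: str = "perfect",
    **spec_kwargs,
) -> SyntheticDataset:
    """A metagene cohort with antisense motifs planted at the three peaks.

    peak1 motifs start at gene-oriented -250, peak2 at +125, peak3 just
    inside intron 1; per-gene Bernoulli planting with the given
    probabilities. The truth ledger records zone labels peak1/peak2/peak3.
    """
    p1, p2, p3 = probabilities
    placements = []
    for zone, p in (("peak1", p1), ("peak2", p2), ("peak3", p3)):
        if p > 0:
            placements.append(
                MotifPlacement(motif_class=motif_class, zone=zone, probability=p)
            )
    spec = SyntheticSpec(
        chrom_lengths=chrom_lengths,
        n_genes=n_genes,
        motif_placements=tuple(placements),
        seed=seed,
        **spec_kwargs,
    )
    return generate(spec)


# ---------------------------------------------------------------------------
# writers


def _write_dataset(ds: SyntheticDataset, out_dir: Path) -> dict[str, Path]:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "genome.fa",
        "gff3": out_dir / "genes.gff3",
        "tes": out_dir / "tes.bed",
        "snps": out_dir / "snps.tsv",
        "go": out_dir / "go_map.tsv",
        "truth_motifs": out_dir / "truth_motifs.tsv",
        "truth_snps": out_dir / "truth_snps.tsv",
    }
    SeqIO.write(
        [SeqRecord(Seq(s), id=c, description="") for c, s in ds.genome.items()],
        paths["fasta"],
        "fasta",
    )
    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ds.truth.genes:
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tg4atlas\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};confidence={g.confidence}\n"
            )
            fh.write(
                f"{g.chrom}\tg4atlas\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for kind, blocks in (("exon", g.exon_blocks), ("CDS", g.cds_blocks)):
                phase = 0
                for bs, be in sorted(blocks):
                    ph = phase if kind == "CDS" else "."
                    fh.write(
                        f"{g.chrom}\tg4atlas\t{kind}\t{bs + 1}\t{be}\t.\t{g.strand}\t"
                        f"{ph}\tParent={mrna}\n"
                    )
    with open(paths["tes"], "w") as fh:
        for chrom, s, e, fam in ds.truth.tes:
            fh.write(f"{chrom}\t{s}\t{e}\t{fam}\n")
    with open(paths["snps"], "w") as fh:
        fh.write("marker_id\tchrom\tpos\tref\talt\n")
        for p in ds.truth.snps:
            s = p.snp
            fh.write(f"{s.marker_id}\t{s.chrom}\t{s.pos + 1}\t{s.ref_allele}\t{s.alt_allele}\n")
    with open(paths["go"], "w") as fh:
        for gene, terms in ds.truth.go_map.items():
            fh.write(f"{gene}\t{','.join(sorted(terms))}\n")
    with open(paths["truth_motifs"], "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tmotif_class\thost_gene\tzone\n")
        for m in ds.truth.motifs:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.strand}\t{m.motif_class}\t"
                f"{m.host_gene or '.'}\t{m.zone}\n"
            )
    with open(paths["truth_snps"], "w") as fh:
        fh.write("marker_id\tzone\tmotif_id\n")
        for p in ds.truth.snps:
            fh.write(f"{p.snp.marker_id}\t{p.zone}\t{p.motif_id or '.'}\n")
    return paths
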