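"""Gene annotation, TE, SNP and GO input handling and motif assignment.

Reads GFF3 gene models (via gffutils), TE intervals (GFF3 or BED), SNP
tables (TSV, 1-based positions converted on read) and GO maps; builds
interval indexes; assigns motifs to gene structural categories; and
classifies whether a SNP disrupts the stems of a motif.

All intervals are 0-based half-open and overlap means >= 1 shared base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .records import G4Motif, SequenceRecord, revcomp
from .scan import greedy_stem_parse, scan_perfect

FEATURE_CATEGORIES = (
    "upstream_1k",
    "downstream_1k",
    "flank5_500",
    "flank3_500",
    "gene_body",
    "cds_first",
    "cds_rest",
    "intron_first",
    "intron_rest",
)


@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered CDS/exon blocks.

    ``cds_blocks`` and ``exon_blocks`` are lists of (start, end) in
    transcription order: for a minus-strand gene the first block is the
    genomically rightmost one. The start codon sits at the first base of the
    first CDS block (on the gene's own strand).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_blocks: tuple[tuple[int, int], ...] = ()
    exon_blocks: tuple[tuple[int, int], ...] = ()
    confidence: str = ""

    @property
    def has_cds(self) -> bool:
        return bool(self.cds_blocks)

    @property
    def n_exons(self) -> int:
        return len(self.exon_blocks)

    def start_codon_pos(self) -> int:
        """Genomic coordinate of the gene-oriented base 0 of the first CDS."""
        if not self.cds_blocks:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        first = self.cds_blocks[0]
        return first[0] if self.strand == "+" else first[1] - 1

    def intron1_start_pos(self) -> int:
        """Genomic coordinate of the first intron's first (gene-oriented) base."""
        if len(self.exon_blocks) < 2:
            raise ValueError(f"gene {self.gene_id} has < 2 exons")
        first = self.exon_blocks[0]
        return first[1] if self.strand == "+" else first[0] - 1

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in transcription order (genomic coordinates)."""
        out = []
        for a, b in zip(self.exon_blocks, self.exon_blocks[1:]):
            if self.strand == "+":
                out.append((a[1], b[0]))
            else:
                out.append((b[1], a[0]))
        return out

    def to_offset(self, pos: int, anchor: int) -> int:
        """Gene-oriented offset of genomic base ``pos`` relative to ``anchor``."""
        return pos - anchor if self.strand == "+" else anchor - pos


@dataclass(frozen=True)
class SNPRecord:
    marker_id: str
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for a in (self.ref_allele, self.alt_allele):
            if a not in ("A", "C", "G", "T"):
                raise ValueError(f"SNP {self.marker_id}: allele {a!r} not a single base")


@dataclass
class FeatureAssignment:
    motif_id: str
    categories: set[str] = field(default_factory=set)
    gene_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers


def read_genes(gff3_path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 into gene models (first transcript per gene, file order).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Genes without CDS children are retained with empty ``cds_blocks``.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(g, featuretype=("mRNA", "transcript"), order_by="start"))
        parent = mrnas[0] if mrnas else g
        cds = [(f.start - 1, f.end) for f in db.children(parent, featuretype="CDS")]
        exons = [(f.start - 1, f.end) for f in db.children(parent, featuretype="exon")]
        cds.sort()
        exons.sort()
        if not exons and cds:
            exons = list(cds)
        if g.strand == "-":
            cds = cds[::-1]
            exons = exons[::-1]
        conf = ""
        for key in ("confidence", "primconf", "class"):
            if key in g.attributes:
                conf = g.attributes[key][0]
                break
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                cds_blocks=tuple(cds),
                exon_blocks=tuple(exons),
                confidence=conf,
            )
        )
    return genes


def read_te_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """TE intervals as (chrom, start, end, family) from BED or GFF3.

    BED is taken as 0-based half-open with the family in column 4; GFF3 is
    1-based inclusive with the family from the ``type`` column (or a
    ``family`` attribute when present).
    """
    path = Path(path)
    rows: list[tuple[str, int, int, str]] = []
    is_gff = path.suffix.lower() in (".gff", ".gff3")
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if is_gff:
                    fam = f[2]
                    for kv in f[8].split(";") if len(f) > 8 else []:
                        if kv.startswith("family="):
                            fam = kv.split("=", 1)[1]
                    rows.append((f[0], int(f[3]) - 1, int(f[4]), fam))
                else:
                    fam = f[3] if len(f) > 3 else "TE"
                    rows.append((f[0], int(f[1]), int(f[2]), fam))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: unparseable TE line") from exc
    return rows


def read_snps(path: str | Path, genome: dict[str, str] | None = None) -> list[SNPRecord]:
    """SNP TSV (marker_id, chrom, 1-based pos, ref, alt) -> 0-based records.

    With ``genome`` supplied, the reference allele is checked against the
    genome base at the SNP position.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (ln == 1 and line.lower().startswith("marker")):
                continue
            f = line.split("\t")
            try:
                rec = SNPRecord(f[0], f[1], int(f[2]) - 1, f[3].upper(), f[4].upper())
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: unparseable SNP line") from exc
            if genome is not None:
                base = genome[rec.chrom][rec.pos]
                if base != rec.ref_allele:
                    raise ValueError(
                        f"{path}:{ln}: ref allele {rec.ref_allele} does not match "
                        f"genome base {base} at {rec.chrom}:{rec.pos + 1}"
                    )
            out.append(rec)
    return out


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """GO map TSV: ``gene_id<TAB>GO:NNNNNNN[,GO:...]`` -> dict of term sets."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, _, terms = line.partition("\t")
            out.setdefault(gene, set()).update(
                t for t in terms.split(",") if t.strip()
            )
    return out


# ---------------------------------------------------------------------------
# assignment


def _gene_category_intervals(
    gene: GeneModel, flank_small: int, flank_large: int
) -> list[tuple[str, int, int]]:
    s, e = gene.start, gene.end
    if gene.strand == "+":
        up_l, up_s = (s - flank_large, s), (s - flank_small, s)
        dn_l, dn_s = (e, e + flank_large), (e, e + flank_small)
    else:
        up_l, up_s = (e, e + flank_large), (e, e + flank_small)
        dn_l, dn_s = (s - flank_large, s), (s - flank_small, s)
    out = [
        ("upstream_1k", *up_l),
        ("flank5_500", *up_s),
        ("downstream_1k", *dn_l),
        ("flank3_500", *dn_s),
        ("gene_body", s, e),
    ]
    introns = gene.introns()
    for label, blocks in (("cds", gene.cds_blocks), ("intron", introns)):
        for i, (bs, be) in enumerate(blocks):
            out.append((f"{label}_{'first' if i == 0 else 'rest'}", bs, be))
    return [(c, max(a, 0), b) for c, a, b in out if b > max(a, 0)]


def assign_motifs(
    motifs: list[G4Motif],
    genes: list[GeneModel],
    flank_small: int = 500,
    flank_large: int = 1000,
) -> list[FeatureAssignment]:
    """Assign each motif every gene-structural category it overlaps by >=1 bp.

    A motif may hit several genes; categories are unioned across genes, but
    cds_first vs cds_rest (and intron_first vs intron_rest) are resolved per
    (motif, gene): overlap with the first block wins.
    """
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes):
        lo, hi = g.start - flank_large, g.end + flank_large
        trees.setdefault(g.chrom, IntervalTree()).addi(max(lo, 0), hi, gi)
    out = []
    for m in motifs:
        fa = FeatureAssignment(motif_id=m.id)
        tree = trees.get(m.chrom)
        if tree is None:
            out.append(fa)
            continue
        for hit in sorted(tree.overlap(m.start, m.end), key=lambda h: h.data):
            g = genes[hit.data]
            cats = set()
            for cat, a, b in _gene_category_intervals(g, flank_small, flank_large):
                if m.start < b and m.end > a:
                    cats.add(cat)
            for stem_cat in ("cds", "intron"):
                if f"{stem_cat}_first" in cats:
                    cats.discard(f"{stem_cat}_rest")
            if cats:
                fa.categories |= cats
                fa.gene_ids.append(g.gene_id)
        out.append(fa)
    return out


def genes_with_g4(
    motifs: list[G4Motif], genes: list[GeneModel], flank: int = 500
) -> set[str]:
    """Gene ids whose body +- ``flank`` bp overlaps at least one motif."""
    trees: dict[str, IntervalTree] = {}
    for m in motifs:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end)
    hit = set()
    for g in genes:
        tree = trees.get(g.chrom)
        if tree and tree.overlap(max(g.start - flank, 0), g.end + flank):
            hit.add(g.gene_id)
    return hit


def overlap_tes(
    motifs: list[G4Motif], te_intervals: list[tuple[str, int, int, str]]
) -> tuple[int, float, dict[str, int]]:
    """Motifs overlapping TEs: (count, fraction of motifs, per-family tallies).

    A motif inside nested TEs counts once toward the total; family tallies
    count each distinct overlapping family once per motif.
    """
    if not motifs:
        return 0, 0.0, {}
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, fam in te_intervals:
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e, fam)
    n_in = 0
    fam_counts: dict[str, int] = {}
    for m in motifs:
        tree = trees.get(m.chrom)
        if not tree:
            continue
        fams = {h.data for h in tree.overlap(m.start, m.end)}
        if fams:
            n_in += 1
            for f in fams:
                fam_counts[f] = fam_counts.get(f, 0) + 1
    return n_in, n_in / len(motifs), fam_counts


def snps_in_motifs(
    motifs: list[G4Motif], snps: list[SNPRecord]
) -> list[tuple[SNPRecord, str, int]]:
    """(snp, motif_id, offset) for every SNP inside a motif's [start, end)."""
    trees: dict[str, IntervalTree] = {}
    for m in motifs:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, m)
    out = []
    for snp in snps:
        tree = trees.get(snp.chrom)
        if not tree:
            continue
        for h in sorted(tree.overlap(snp.pos, snp.pos + 1), key=lambda h: h.begin):
            out.append((snp, h.data.id, snp.pos - h.begin))
    return out


SNP_FLANK = 10


def classify_snp_disruption(
    motif: G4Motif, snp: SNPRecord, genome: dict[str, str]
) -> str:
    """Classify a SNP's effect on a perfect-pattern motif.

    Returns one of ``stem_disruptive``, ``stem_tolerated``, ``loop_or_flank``.
    A SNP in a loop of the greedy parse (or in the +-10 bp flank) cannot
    unstack a quartet; a SNP in a stem is applied to the sequence and the
    neighbourhood rescanned — if a perfect motif still overlaps the original
    span on the same strand (redundant G-runs sliding over the lesion), the
    change is tolerated, otherwise it is disruptive.
    """
    if motif.motif_class not in ("perfect", "multimeric"):
        raise ValueError("SNP disruption classification requires a perfect-pattern motif")
    if snp.chrom != motif.chrom:
        raise ValueError("SNP and motif are on different chromosomes")
    if not (motif.start - SNP_FLANK <= snp.pos < motif.end + SNP_FLANK):
        raise ValueError("SNP outside the motif and its +-10 bp flank")
    if not (motif.start <= snp.pos < motif.end):
        return "loop_or_flank"
    # position of the SNP in the motif as read 5'->3' on the folding strand
    off = snp.pos - motif.start if motif.strand == "+" else motif.end - 1 - snp.pos
    min_stems = 8 if motif.motif_class == "multimeric" else 4
    stems = greedy_stem_parse(motif.motif_seq, min_stems=min_stems)
    if not any(s <= off < e for s, e in stems):
        return "loop_or_flank"
    seq = genome[motif.chrom]
    lo = max(motif.start - SNP_FLANK, 0)
    hi = min(motif.end + SNP_FLANK, len(seq))
    window = list(seq[lo:hi])
    window[snp.pos - lo] = snp.alt_allele
    mutated = "".join(window)
    if motif.strand == "-":
        probe, m_lo = revcomp(mutated), hi - motif.end
    else:
        probe, m_lo = mutated, motif.start - lo
    m_hi = m_lo + (motif.end - motif.start)
    rec = SequenceRecord("w", probe)
    for m in scan_perfect(rec, min_stems=min_stems):
        if m.start < m_hi and m.end > m_lo:
            return "stem_tolerated"
    return "stem_disruptive"
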