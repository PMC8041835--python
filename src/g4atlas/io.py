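"""FASTA and BED input/output for motif records."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .records import G4Motif, MergedMotif, SequenceRecord


def load_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA; sequences are uppercased and validated."""
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_motifs_bed(motifs: list[G4Motif], path: str | Path) -> None:
    """BED6+ motif track: name=class:id, score=n_stems, extra column motif_seq."""
    with open(path, "w") as fh:
        for i, m in enumerate(motifs, 1):
            name = f"{m.motif_class}:{i}"
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{name}\t{m.n_stems}\t{m.strand}\t"
                f"{m.motif_seq}\n"
            )


def read_motifs_bed(path: str | Path) -> list[G4Motif]:
    """Read motifs back from the BED6+ track written by :func:`write_motifs_bed`."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                cls = f[3].split(":")[0]
                out.append(
                    G4Motif(
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        strand=f[5],
                        motif_seq=f[6],
                        n_stems=int(f[4]),
                        motif_class=cls,
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: unparseable motif BED line") from exc
    return out
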