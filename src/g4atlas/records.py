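"""Core value types shared across the package.

Coordinates are 0-based half-open throughout, BED-style. GFF3 input is
converted on read. A motif on the minus strand is stored with forward-strand
coordinates; its ``motif_seq`` is the reverse complement of the forward slice,
i.e. the G-rich sequence as read 5'->3' on the strand that folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MOTIF_CLASSES = ("perfect", "multimeric", "imperfect", "imperfect_long")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


def validate_alphabet(seq: str, name: str = "sequence") -> None:
    for i, c in enumerate(seq):
        if c not in VALID_BASES:
            raise AlphabetError(
                f"{name}: invalid character {c!r} at position {i} "
                "(expected A/C/G/T/N)"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase nucleotide sequence over {A,C,G,T,N}.

    Input is uppercased on construction; soft-masked (lowercase) bases are
    treated the same as uppercase ones.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} is empty")
        up = self.seq.upper()
        if up is not self.seq:
            object.__setattr__(self, "seq", up)
        validate_alphabet(self.seq, name=self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class G4Motif:
    """A scanned G-quadruplex motif interval.

    ``n_stems`` is the number of G-runs consumed by the greedy parse of the
    motif on its own strand; ``motif_class`` is one of
    perfect / multimeric / imperfect / imperfect_long.
    """

    chrom: str
    start: int
    end: int
    strand: str
    motif_seq: str
    n_stems: int
    motif_class: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad motif interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if len(self.motif_seq) != self.end - self.start:
            raise ValueError("motif_seq length does not match interval span")

    @property
    def id(self) -> str:
        return f"{self.motif_class}:{self.chrom}:{self.start}-{self.end}:{self.strand}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MergedMotif(G4Motif):
    """An imperfect motif after merging overlapping candidates.

    ``n_candidates`` counts the pre-merge candidate intervals collapsed into
    this record.
    """

    n_candidates: int = 1
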