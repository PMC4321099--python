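"""RNA sequence containers and FASTA I/O for the target-prediction arm.

miRNAs are held 5'->3' in the RNA alphabet; 3'UTRs may arrive as DNA and are
canonicalized (T -> U, uppercase) at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import SequenceError

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SEED_START = 2  # 1-based miRNA position, inclusive
SEED_END = 8


def canonicalize(sequence: str) -> str:
    """Uppercase and map T->U; reject non-canonical characters."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"non-canonical characters: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement in the RNA alphabet (A<->U, G<->C)."""
    return canonicalize(sequence).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNASeq:
    """A mature miRNA, 5'->3'.  The seed is positions 2-8 (1-based)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonicalize(self.sequence))
        if not 18 <= len(self.sequence) <= 26:
            raise SequenceError(
                f"{self.id}: mature miRNA length {len(self.sequence)} outside 18-26 nt")

    @property
    def seed(self) -> str:
        return self.sequence[SEED_START - 1:SEED_END]


@dataclass(frozen=True)
class UTRSeq:
    """A 3'UTR, 5'->3', canonicalized to the RNA alphabet."""

    gene_id: str
    sequence: str
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.gene_id}: empty UTR sequence")
        object.__setattr__(self, "sequence", canonicalize(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def read_mirna_fasta(path: str | Path) -> list[MiRNASeq]:
    return [MiRNASeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_utr_fasta(path: str | Path) -> list[UTRSeq]:
    """Read UTRs; a second whitespace token in the header is the accession."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        accession = parts[1] if len(parts) > 1 else ""
        out.append(UTRSeq(rec.id, str(rec.seq), accession=accession))
    return out
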