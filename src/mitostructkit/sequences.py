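"""Circular sequence container and FASTA I/O helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["CircularSequence", "revcomp", "read_fasta", "write_fasta"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class CircularSequence:
    """A circular nucleotide molecule.

    Coordinates are 0-based half-open on the forward strand; an interval may
    have end > len(seq), meaning it wraps across the origin. ``features``
    carries planted-feature annotations for synthetic genomes.
    """

    id: str
    seq: str
    features: Dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Substring [start, end) with circular wrap-around."""
        L = len(self.seq)
        length = end - start
        if length < 0 or length > L:
            raise ValueError("interval length must be in [0, molecule length]")
        start %= L
        return (self.seq + self.seq)[start : start + length]

    def rotate(self, offset: int) -> "CircularSequence":
        L = len(self.seq)
        offset %= L
        return CircularSequence(self.id, self.seq[offset:] + self.seq[:offset], dict(self.features))


def read_fasta(path: str | Path) -> List[CircularSequence]:
    return [CircularSequence(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[CircularSequence], path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")
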