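"""In-memory genome sequences.

A :class:`GenomeSequence` is an ordered mapping of contig name to a mutable
uppercase DNA sequence (``bytearray``).  It is the substrate both for the
synthetic-genome simulator (which plants motifs in place) and for the
G4Hunter scorer.  FASTA round-trips go through Biopython.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = bytes.maketrans(b"ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                              b"TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str | bytes | bytearray) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return bytes(seq).translate(_COMPLEMENT)[::-1].decode()


@dataclass
class GenomeSequence:
    """Named contigs of A/C/G/T/N held as mutable byte arrays."""

    contigs: Dict[str, bytearray] = field(default_factory=dict)

    def add(self, name: str, sequence: str | bytes | bytearray) -> None:
        if name in self.contigs:
            raise ValueError(f"duplicate contig {name!r}")
        if isinstance(sequence, str):
            sequence = sequence.encode()
        self.contigs[name] = bytearray(sequence).upper()

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def items(self) -> Iterator[Tuple[str, bytearray]]:
        return iter(self.contigs.items())

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def fetch(self, name: str, start: int = 0, end: int | None = None) -> str:
        """Return the sequence of ``name[start:end)`` as an uppercase string."""
        seq = self.contigs[name]
        if end is None:
            end = len(seq)
        if start < 0 or end > len(seq) or end < start:
            raise ValueError(
                f"window [{start}, {end}) outside contig {name!r} "
                f"of length {len(seq)}")
        return seq[start:end].decode()

    def replace(self, name: str, start: int, sequence: str) -> None:
        """Overwrite bases in place (used by the motif planter)."""
        seq = self.contigs[name]
        end = start + len(sequence)
        if start < 0 or end > len(seq):
            raise ValueError(
                f"replacement [{start}, {end}) outside contig {name!r}")
        seq[start:end] = sequence.upper().encode()

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        records = [
            SeqRecord(Seq(seq.decode()), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
            writer.write_file(records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        genome = cls()
        with open(path) as handle:
            for record in SeqIO.parse(handle, "fasta"):
                genome.add(record.id, str(record.seq))
        return genome

    def to_fasta_str(self, width: int = 60) -> str:
        buf = io.StringIO()
        records = [
            SeqRecord(Seq(seq.decode()), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        writer = SeqIO.FastaIO.FastaWriter(buf, wrap=width)
        writer.write_file(records)
        return buf.getvalue()
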