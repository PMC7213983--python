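"""Amino-acid alignments over the 20-state alphabet plus gap.

FASTA I/O goes through Biopython; the class itself only enforces the
invariants the reconstruction code relies on (equal lengths, legal alphabet,
unique names).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical state order used everywhere: alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_LEGAL = set(AMINO_ACIDS) | {GAP}

__all__ = ["AMINO_ACIDS", "GAP", "AlignmentError", "Alignment"]


class AlignmentError(ValueError):
    """Raised on malformed alignments (ragged lengths, illegal characters)."""


@dataclass
class Alignment:
    """An ordered set of equal-length amino-acid sequences."""

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names and sequences differ in count")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("sequence names are not unique")
        if self.sequences:
            L = len(self.sequences[0])
            for name, seq in zip(self.names, self.sequences):
                if len(seq) != L:
                    raise AlignmentError(
                        f"sequence {name!r} has length {len(seq)}, expected {L}"
                    )
                bad = set(seq) - _LEGAL
                if bad:
                    raise AlignmentError(
                        f"sequence {name!r} contains illegal characters {sorted(bad)}"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> str:
        try:
            return self.sequences[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(names, seqs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in zip(self.names, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
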