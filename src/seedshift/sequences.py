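"""Nucleotide sequence handling.

All sequences are held 5'->3' over the RNA alphabet {A, C, G, U}; DNA input
(T) is normalized to U on construction.  FASTA I/O goes through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


class SequenceError(ValueError):
    """Raised for malformed nucleotide input."""


def normalize_residues(residues: str) -> str:
    """Uppercase, convert T->U and validate against the RNA alphabet."""
    s = residues.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid residues {sorted(bad)!r} in sequence")
    if not s:
        raise SequenceError("empty sequence")
    return s


@dataclass(frozen=True)
class NucSequence:
    """A named RNA sequence, 5'->3'."""

    id: str
    residues: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def subseq(self, start: int, end: int, id: str | None = None) -> "NucSequence":
        return NucSequence(id or f"{self.id}[{start}:{end}]", self.residues[start:end])

    def with_substitution(self, position: int, base: str, id: str | None = None) -> "NucSequence":
        base = normalize_residues(base)
        if len(base) != 1:
            raise SequenceError("substitution must be a single residue")
        r = self.residues
        if not 0 <= position < len(r):
            raise SequenceError(f"position {position} outside sequence of length {len(r)}")
        return NucSequence(id or self.id, r[:position] + base + r[position + 1:])


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(residues: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(residues))


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a (DNA or RNA) FASTA file into normalized RNA sequences."""
    return [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[NucSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def random_rna(rng, length: int, gc: float = 0.5) -> str:
    """Random RNA string with expected GC content ``gc`` (i.i.d. bases)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "U"], size=length, p=p))
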