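"""Nucleotide alphabets, validated sequences, and elementary transforms.

Every other module builds on :class:`NucleotideSequence` (an immutable,
alphabet-checked RNA or DNA string with linear or circular topology) and
:class:`MiRNA` (a mature microRNA with its seed region).

Coordinate conventions: internal arithmetic is 0-based half-open; anything
user-facing (seed ranges, bulge windows, duplex positions, GenBank output)
is 1-based inclusive, the convention molecular biologists expect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

from Bio.Seq import Seq
from Bio.SeqIO import parse as _seqio_parse

__all__ = [
    "Alphabet",
    "Topology",
    "NucleotideSequence",
    "MiRNA",
    "SequenceError",
    "reverse_complement",
    "transcribe",
    "back_transcribe",
    "seed_of",
    "read_mirna_fasta",
    "write_mirna_fasta",
]


class SequenceError(ValueError):
    """Raised for invalid residues, alphabets, or topology misuse."""


class Alphabet(Enum):
    RNA = "RNA"
    DNA = "DNA"

    @property
    def letters(self) -> frozenset:
        return _LETTERS[self]


class Topology(Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


_LETTERS = {
    Alphabet.RNA: frozenset("ACGU"),
    Alphabet.DNA: frozenset("ACGT"),
}


def _min_rotation(s: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm)."""
    ss = s + s
    n = len(s)
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + n]


@dataclass(frozen=True, eq=False)
class NucleotideSequence:
    """A validated nucleotide string with declared alphabet and topology.

    Residues are upper-cased on construction; ambiguity codes (N, R, Y, ...)
    are rejected because the downstream design procedure is undefined for
    ambiguous bases. Two circular sequences compare equal iff one is a
    rotation of the other (canonicalized via the minimal rotation).
    """

    residues: str
    alphabet: Alphabet = Alphabet.RNA
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        res = self.residues.upper()
        object.__setattr__(self, "residues", res)
        if not res:
            raise SequenceError("sequence must be non-empty")
        bad = set(res) - self.alphabet.letters
        if bad:
            raise SequenceError(
                f"invalid {self.alphabet.value} residues: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR

    def canonical(self) -> str:
        """Residues in canonical form (minimal rotation if circular)."""
        if self.is_circular:
            return _min_rotation(self.residues)
        return self.residues

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NucleotideSequence):
            return NotImplemented
        return (
            self.alphabet is other.alphabet
            and self.topology is other.topology
            and self.canonical() == other.canonical()
        )

    def __hash__(self) -> int:
        return hash((self.alphabet, self.topology, self.canonical()))

    # --- convenience wrappers over the module-level transforms ---

    def reverse_complement(self) -> "NucleotideSequence":
        return reverse_complement(self)

    def transcribe(self) -> "NucleotideSequence":
        return transcribe(self)

    def back_transcribe(self) -> "NucleotideSequence":
        return back_transcribe(self)


def reverse_complement(s: NucleotideSequence) -> NucleotideSequence:
    """Reverse complement in the same alphabet; length and topology preserved."""
    if s.alphabet is Alphabet.RNA:
        rc = str(Seq(s.residues).reverse_complement_rna())
    else:
        rc = str(Seq(s.residues).reverse_complement())
    return NucleotideSequence(rc, s.alphabet, s.topology)


def transcribe(s: NucleotideSequence) -> NucleotideSequence:
    """DNA sense strand -> RNA (T becomes U)."""
    if s.alphabet is not Alphabet.DNA:
        raise SequenceError("transcribe expects a DNA sequence")
    return NucleotideSequence(s.residues.replace("T", "U"), Alphabet.RNA, s.topology)


def back_transcribe(s: NucleotideSequence) -> NucleotideSequence:
    """RNA -> DNA sense strand (U becomes T)."""
    if s.alphabet is not Alphabet.RNA:
        raise SequenceError("back_transcribe expects an RNA sequence")
    return NucleotideSequence(s.residues.replace("U", "T"), Alphabet.DNA, s.topology)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: identifier, 5'->3' RNA sequence, and seed region.

    The seed (default positions 2-8, 1-based inclusive) is the primary
    determinant of target recognition.
    """

    id: str
    seq: NucleotideSequence
    seed_range: tuple = (2, 8)

    def __post_init__(self) -> None:
        if self.seq.alphabet is not Alphabet.RNA:
            raise SequenceError(f"miRNA {self.id!r} must be RNA")
        if self.seq.topology is not Topology.LINEAR:
            raise SequenceError(f"miRNA {self.id!r} must be linear")
        if len(self.seq) < 15:
            raise SequenceError(
                f"miRNA {self.id!r} is {len(self.seq)} nt; expected >= 15"
            )
        lo, hi = self.seed_range
        if not (1 <= lo <= hi <= len(self.seq)):
            raise SequenceError(
                f"seed_range {self.seed_range} outside [1, {len(self.seq)}]"
            )

    @classmethod
    def from_string(cls, id: str, residues: str, seed_range: tuple = (2, 8)) -> "MiRNA":
        return cls(id, NucleotideSequence(residues, Alphabet.RNA), seed_range)

    def __len__(self) -> int:
        return len(self.seq)


def seed_of(m: MiRNA) -> NucleotideSequence:
    """The seed subsequence at ``m.seed_range`` (1-based inclusive)."""
    lo, hi = m.seed_range
    return NucleotideSequence(m.seq.residues[lo - 1 : hi], Alphabet.RNA)


# --- miRBase-dialect FASTA ---


def read_mirna_fasta(source: Union[str, Path, io.TextIOBase]) -> list:
    """Read a miRNA panel from FASTA text, a path, or an open handle.

    Headers like ``>hsa-miR-21-5p MIMAT0000076 Homo sapiens miR-21-5p`` are
    tolerated: the first whitespace-separated token is the id. T residues
    are accepted and converted to U (some miRBase exports are DNA-alphabet).
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle: io.TextIOBase = open(source)
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source
        close = False
    try:
        panel = []
        for rec in _seqio_parse(handle, "fasta"):
            residues = str(rec.seq).upper().replace("T", "U")
            panel.append(MiRNA.from_string(rec.id, residues))
        return panel
    finally:
        if close:
            handle.close()


def write_mirna_fasta(mirnas: Iterable[MiRNA]) -> str:
    """FASTA text for a miRNA panel, 60-column wrapped."""
    out = []
    for m in mirnas:
        out.append(f">{m.id}")
        res = m.seq.residues
        out.extend(res[i : i + 60] for i in range(0, len(res), 60))
    return "\n".join(out) + ("\n" if out else "")
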