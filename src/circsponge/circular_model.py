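"""Sequence-level model of back-splicing the sponge insert.

In the expression vector the insert sits between two inverted ALU
elements downstream of the CMV promoter; their complementarity brings the
flanking splice sites together so the insert is excised and covalently
closed into a circle during back-splicing. Only the circularized region
is modelled here — the ALU arms, promoter, and the EGFP reporter (which
lies outside the ALU pair) are not part of the circle. The EcoRV/SacII
flank bases lie inside the circularized region and are retained.

The canonical rotation starts at the first base of flank5, so coordinates
on the circle line up with coordinates on the insert, and the back-splice
junction is the point where the insert's 3' end meets its 5' start.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_core import Alphabet, NucleotideSequence, SequenceError, Topology, transcribe
from .sponge_design import SpongeConstruct

__all__ = ["CircTranscript", "backsplice", "rotate", "junction_window"]


@dataclass(frozen=True)
class CircTranscript:
    """A covalently closed sponge transcript."""

    seq: NucleotideSequence  # RNA, circular
    origin: str  # id of the construct/target it was derived from
    junction_offset: int = 0  # junction position in the canonical rotation

    def __post_init__(self) -> None:
        if self.seq.topology is not Topology.CIRCULAR:
            raise SequenceError("CircTranscript requires circular topology")
        if self.seq.alphabet is not Alphabet.RNA:
            raise SequenceError("CircTranscript requires RNA")

    def __len__(self) -> int:
        return len(self.seq)

    def linearize(self) -> NucleotideSequence:
        """Open the circle at the junction: the transcript of the insert."""
        res = self.seq.residues
        k = self.junction_offset % len(res)
        return NucleotideSequence(res[k:] + res[:k], Alphabet.RNA, Topology.LINEAR)


def backsplice(c: SpongeConstruct) -> CircTranscript:
    """Circularize the insert: join its transcript end-to-start."""
    rna = transcribe(c.insert)
    return CircTranscript(
        seq=NucleotideSequence(rna.residues, Alphabet.RNA, Topology.CIRCULAR),
        origin=c.target,
        junction_offset=0,
    )


def rotate(s: NucleotideSequence, k: int) -> NucleotideSequence:
    """Rotate a circular sequence by k positions (mod length).

    The result equals the input under circular equality; linear input is a
    topology error.
    """
    if s.topology is not Topology.CIRCULAR:
        raise SequenceError("rotate requires a circular sequence")
    n = len(s)
    k %= n
    return NucleotideSequence(
        s.residues[k:] + s.residues[:k], s.alphabet, Topology.CIRCULAR
    )


def junction_window(t: CircTranscript, w: int) -> NucleotideSequence:
    """The 2w bases centred on the back-splice junction, as linear RNA.

    Returns the last w bases of the canonical rotation joined to its first
    w bases — the target region for junction-spanning RT-PCR primers that
    detect the circle but not the linear precursor.
    """
    n = len(t)
    if w < 1 or 2 * w > n:
        raise SequenceError(f"window half-width {w} invalid for circle of length {n}")
    lin = t.linearize().residues
    return NucleotideSequence(lin[-w:] + lin[:w], Alphabet.RNA, Topology.LINEAR)
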