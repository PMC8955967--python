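"""Positional, gap-free antiparallel pairing between a miRNA and a site.

The model is deliberately simple: the miRNA and a same-length site are
paired position-by-position in antiparallel orientation (miRNA position p
against site position L+1-p), and each position is classified Watson-Crick
('|'), G:U wobble ('o'), or mismatch ('.'). This matches the geometry of a
bulged sponge binding site, where the "bulge" is an equal-length block of
deliberate mismatches rather than an asymmetric loop, so no gaps are
needed. Thermodynamic folding is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .seq_core import Alphabet, MiRNA, NucleotideSequence, SequenceError

__all__ = [
    "WC_PAIRS",
    "WOBBLE_PAIRS",
    "is_wc",
    "is_wobble",
    "wc_complement",
    "DuplexReport",
    "pair_duplex",
]

#: Watson-Crick pairs over the RNA alphabet, (miRNA base, site base).
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})

#: G:U wobble pairs, permitted in RNA duplexes but treated as non-pairing
#: for site classification throughout this package.
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def is_wc(x: str, y: str) -> bool:
    return (x, y) in WC_PAIRS


def is_wobble(x: str, y: str) -> bool:
    return (x, y) in WOBBLE_PAIRS


def wc_complement(base: str) -> str:
    """Watson-Crick complement of a single RNA base."""
    return _RNA_COMPLEMENT[base]


@dataclass(frozen=True)
class DuplexReport:
    """Per-position pairing record between a miRNA and one binding site.

    ``pairing[p-1]`` describes miRNA position p (1-based, 5'->3' on the
    miRNA): '|' Watson-Crick, 'o' G:U wobble, '.' mismatch.
    """

    mirna_id: str
    site: NucleotideSequence
    pairing: str
    site_start: int = 0
    wc_weight: float = 1.0
    wobble_weight: float = 0.5
    mismatch_weight: float = -1.0

    @property
    def n_wc(self) -> int:
        return self.pairing.count("|")

    @property
    def n_wobble(self) -> int:
        return self.pairing.count("o")

    @property
    def n_mismatch(self) -> int:
        return self.pairing.count(".")

    @property
    def score(self) -> float:
        return (
            self.wc_weight * self.n_wc
            + self.wobble_weight * self.n_wobble
            + self.mismatch_weight * self.n_mismatch
        )

    def mismatch_positions(self) -> set:
        """1-based miRNA positions classified as mismatch."""
        return {i + 1 for i, c in enumerate(self.pairing) if c == "."}

    def wobble_positions(self) -> set:
        return {i + 1 for i, c in enumerate(self.pairing) if c == "o"}

    def render_text(self, mirna_seq: str) -> str:
        """Pretty duplex: miRNA 3'->5' over the site 5'->3'.

        The pairing string is miRNA-indexed, so it is reversed to align
        with the site orientation.
        """
        return "\n".join(
            [
                f"miRNA 3'-{mirna_seq[::-1]}-5'",
                f"         {self.pairing[::-1]}",
                f"site  5'-{self.site.residues}-3'",
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "mirna_id": self.mirna_id,
                "site": self.site.residues,
                "site_start": self.site_start,
                "pairing": self.pairing,
                "n_wc": self.n_wc,
                "n_wobble": self.n_wobble,
                "n_mismatch": self.n_mismatch,
                "score": self.score,
            },
            indent=2,
        )


def pair_duplex(
    m: MiRNA,
    site: NucleotideSequence,
    site_start: int = 0,
    wc_weight: float = 1.0,
    wobble_weight: float = 0.5,
    mismatch_weight: float = -1.0,
) -> DuplexReport:
    """Classify every position of an antiparallel miRNA:site duplex.

    ``site`` is the binding site 5'->3' in the sponge-transcript sense and
    must have the miRNA's length; miRNA position p faces site position
    L+1-p. Score defaults to n_wc + 0.5*n_wobble - n_mismatch.
    """
    if site.alphabet is not Alphabet.RNA:
        site = site.transcribe() if site.alphabet is Alphabet.DNA else site
    L = len(m)
    if len(site) != L:
        raise SequenceError(
            f"site length {len(site)} != miRNA length {L}; the duplex model is gap-free"
        )
    chars = []
    for p in range(1, L + 1):
        x = m.seq.residues[p - 1]
        y = site.residues[L - p]
        if is_wc(x, y):
            chars.append("|")
        elif is_wobble(x, y):
            chars.append("o")
        else:
            chars.append(".")
    return DuplexReport(
        mirna_id=m.id,
        site=site,
        pairing="".join(chars),
        site_start=site_start,
        wc_weight=wc_weight,
        wobble_weight=wobble_weight,
        mismatch_weight=mismatch_weight,
    )
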