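"""Seeded generators of miRNA-like sequences and decoy panels.

These produce the synthetic inputs used by tests, demos, and the
off-target checks of the validator: random miRNA-like sequences with
controlled length and GC content, and decoy panels guaranteed to share no
6mer seed complement with a chosen target.

``MIR21`` is the mature hsa-miR-21-5p sequence as catalogued in miRBase
(MIMAT0000076), the worked-example target throughout the package.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .duplex_report import wc_complement
from .seq_core import MiRNA, NucleotideSequence, Alphabet

__all__ = [
    "MIR21",
    "FixtureSpec",
    "random_mirna",
    "random_design_target",
    "generate_decoy_panel",
]

MIR21 = MiRNA.from_string("hsa-miR-21-5p", "UAGCUUAUCAGACUGAUGUUGA")

_RNA_BASES = "ACGU"


class PanelError(RuntimeError):
    """Rejection-sampling budget exhausted while building a decoy panel."""


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible synthetic miRNA panel."""

    n_mirnas: int = 20
    length_range: tuple = (20, 24)
    gc_range: tuple = (0.2, 0.8)
    rng_seed: int = 42
    exclude_shared_seed: bool = True  # no 6mer seed complement shared with target

    def __post_init__(self) -> None:
        if self.n_mirnas < 0:
            raise ValueError("n_mirnas must be >= 0")
        lo, hi = self.length_range
        if not (15 <= lo <= hi):
            raise ValueError("length_range must lie within [15, inf)")


def random_mirna(rng: random.Random, spec: FixtureSpec, id: str) -> MiRNA:
    """One random miRNA-like sequence meeting the length and GC bounds."""
    lo, hi = spec.length_range
    glo, ghi = spec.gc_range
    while True:
        n = rng.randint(lo, hi)
        seq = "".join(rng.choice(_RNA_BASES) for _ in range(n))
        gc = (seq.count("G") + seq.count("C")) / n
        if glo <= gc <= ghi:
            return MiRNA.from_string(id, seq)


def random_design_target(
    rng: random.Random,
    spec: FixtureSpec,
    id: str,
    params=None,
    max_attempts: int = 10000,
) -> MiRNA:
    """A random miRNA for which the default sponge design is feasible.

    A sponge cannot be cloned if its own binding sites embed one of the
    flanking or forbidden restriction recognition sequences — for such a
    target a scientist would pick different enzymes. This generator
    rejects candidates whose designed MBS (or an MBS/flank junction)
    contains a forbidden recognition sequence, so that every returned
    target yields a construct passing the standard validator.
    """
    from .seq_core import back_transcribe
    from .sponge_design import DesignParams, build_mbs

    if params is None:
        params = DesignParams()
    patterns = {
        e.recognition.residues
        for e in set(params.forbidden_enzymes) | {params.flank5, params.flank3}
    }
    flank5 = params.flank5.recognition.residues
    flank3 = params.flank3.recognition.residues

    def spans_joint(left: str, right: str) -> bool:
        text = left + right
        return any(
            text.find(pat, max(0, len(left) - len(pat) + 1), len(left) + len(pat) - 1)
            != -1
            for pat in patterns
        )

    for _ in range(max_attempts):
        cand = random_mirna(rng, spec, id)
        mbs_dna = back_transcribe(build_mbs(cand, params).seq).residues
        if any(p in mbs_dna for p in patterns):
            continue
        if spans_joint(flank5, mbs_dna) or spans_joint(mbs_dna, flank3):
            continue
        if (
            params.spacer_len == 0
            and params.n_mbs > 1
            and spans_joint(mbs_dna, mbs_dna)
        ):
            continue
        return cand
    raise PanelError(f"no feasible design target found in {max_attempts} attempts")


def _seed_core_complement(m: MiRNA) -> str:
    """5'->3' site hexamer complementary to miRNA positions 2-7."""
    return "".join(wc_complement(b) for b in m.seq.residues[1:7])[::-1]


def generate_decoy_panel(
    spec: FixtureSpec, target: MiRNA, max_attempts_per_decoy: int = 10000
) -> list:
    """Seeded random decoys sharing no 6mer seed complement with the target.

    A candidate is rejected if its seed-core complement occurs in the
    target's perfect-complement binding site (so a target sponge cannot
    harbour canonical decoy seed matches inside its MBS), or vice versa.
    Deterministic per seed.
    """
    rng = random.Random(spec.rng_seed)
    target_site = target.seq.reverse_complement().residues
    target_core = _seed_core_complement(target)
    panel = []
    for k in range(spec.n_mirnas):
        for _ in range(max_attempts_per_decoy):
            cand = random_mirna(rng, spec, f"decoy-{spec.rng_seed}-{k + 1}")
            if spec.exclude_shared_seed:
                core = _seed_core_complement(cand)
                if core in target_site:
                    continue
                if target_core in cand.seq.reverse_complement().residues:
                    continue
            panel.append(cand)
            break
        else:
            raise PanelError(
                f"could not draw decoy {k + 1} within "
                f"{max_attempts_per_decoy} attempts"
            )
    return panel
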