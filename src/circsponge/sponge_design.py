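"""Generate and validate bulged tandem-MBS sponge inserts.

The design procedure mirrors the construct used to sequester
hsa-miR-21-5p: a run of tandem miRNA binding sites (MBS), each the
reverse complement of the target except for a central bulge of deliberate
mismatches (blocking AGO2-mediated slicing of the sponge), separated by
short spacers, and flanked by restriction recognition sequences for
directional cloning. Defaults follow that construct: 7 MBS, a 4-nt bulge
opposite miRNA positions 10-13, 4-nt spacers, EcoRV/SacII flanks, and
HindIII/EcoRI additionally forbidden inside the insert (they frame the
EGFP reporter elsewhere on the vector).

The bulge window is expressed in miRNA coordinates: for a 22-nt miRNA,
MBS positions 10-13 face miRNA positions 10-13 under antiparallel pairing
(p -> L+1-p), so the two readings coincide for miR-21; for other lengths
the miRNA-coordinate reading is used because the bulge's biological job is
to mispair the miRNA's central region.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from Bio import Restriction as _Restriction

from .duplex_report import is_wc, is_wobble, pair_duplex, wc_complement
from .seq_core import (
    Alphabet,
    MiRNA,
    NucleotideSequence,
    Topology,
    back_transcribe,
    reverse_complement,
    transcribe,
)
from .site_scanner import SiteClass, find_full_sites, find_restriction_sites, find_seed_matches

__all__ = [
    "DesignError",
    "RestrictionEnzyme",
    "enzyme_by_name",
    "MismatchPolicy",
    "SpacerPolicy",
    "DesignParams",
    "MBS",
    "Feature",
    "SpongeConstruct",
    "ValidationReport",
    "build_mbs",
    "make_spacer",
    "assemble_insert",
    "validate_construct",
]


class DesignError(ValueError):
    """Raised when the requested design is infeasible or ill-posed."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named restriction endonuclease and its recognition sequence."""

    name: str
    recognition: NucleotideSequence

    def __post_init__(self) -> None:
        if self.recognition.alphabet is not Alphabet.DNA:
            raise DesignError(f"{self.name}: recognition sequence must be DNA")
        if len(self.recognition) < 4:
            raise DesignError(f"{self.name}: recognition shorter than 4 nt")

    @property
    def is_palindromic(self) -> bool:
        return (
            reverse_complement(self.recognition).residues
            == self.recognition.residues
        )


def enzyme_by_name(name: str) -> RestrictionEnzyme:
    """Look up a canonical recognition sequence from the REBASE tables."""
    try:
        enz = getattr(_Restriction, name)
    except AttributeError as exc:
        raise DesignError(f"unknown restriction enzyme {name!r}") from exc
    return RestrictionEnzyme(name, NucleotideSequence(str(enz.site), Alphabet.DNA))


ECORV = enzyme_by_name("EcoRV")    # GATATC
SACII = enzyme_by_name("SacII")    # CCGCGG
HINDIII = enzyme_by_name("HindIII")  # AAGCTT
ECORI = enzyme_by_name("EcoRI")    # GAATTC


class MismatchPolicy(Enum):
    #: place the miRNA's own base opposite itself — for all four bases this
    #: excludes both WC and G:U pairing and needs no RNG.
    IDENTITY = "identity"
    #: draw uniformly (seeded) from the bases that neither WC- nor
    #: wobble-pair the opposing miRNA base.
    SEEDED_RANDOM = "seeded_random"


class SpacerPolicy(Enum):
    FIXED = "fixed"            # one spacer, reused between every MBS pair
    SEEDED_SEARCH = "seeded_search"  # independent seeded search per gap


@dataclass(frozen=True)
class DesignParams:
    """All tunables of the sponge design procedure."""

    n_mbs: int = 7
    bulge_window: tuple = (10, 13)
    spacer_len: int = 4
    flank5: RestrictionEnzyme = ECORV
    flank3: RestrictionEnzyme = SACII
    forbidden_enzymes: frozenset = frozenset({ECORV, SACII, HINDIII, ECORI})
    mismatch_policy: MismatchPolicy = MismatchPolicy.IDENTITY
    spacer_policy: SpacerPolicy = SpacerPolicy.FIXED
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_mbs < 1:
            raise DesignError("n_mbs must be >= 1")
        if self.spacer_len < 0:
            raise DesignError("spacer_len must be >= 0")
        if self.bulge_window is not None:
            lo, hi = self.bulge_window
            if lo > hi or lo < 1:
                raise DesignError(f"malformed bulge_window {self.bulge_window}")
        object.__setattr__(self, "forbidden_enzymes", frozenset(self.forbidden_enzymes))

    def bulge_positions(self) -> set:
        """1-based miRNA positions inside the bulge (empty if no bulge)."""
        if self.bulge_window is None:
            return set()
        lo, hi = self.bulge_window
        return set(range(lo, hi + 1))

    def validate_for(self, m: MiRNA) -> None:
        """Refuse windows outside the miRNA or overlapping its seed."""
        if self.bulge_window is None:
            return
        lo, hi = self.bulge_window
        if hi > len(m):
            raise DesignError(
                f"bulge_window {self.bulge_window} outside miRNA of length {len(m)}"
            )
        slo, shi = m.seed_range
        if not (hi < slo or lo > shi):
            raise DesignError(
                f"bulge_window {self.bulge_window} overlaps seed {m.seed_range}"
            )


@dataclass(frozen=True)
class MBS:
    """One miRNA binding site, 5'->3' in sponge-transcript sense (RNA)."""

    seq: NucleotideSequence
    bulge_positions_mbs: frozenset  # 1-based MBS positions
    source_mirna: str


@dataclass(frozen=True)
class Feature:
    """Half-open [start, end) slice of the insert; kinds: flank5, MBS, spacer, flank3."""

    name: str
    start: int
    end: int
    kind: str


@dataclass(frozen=True)
class SpongeConstruct:
    """The assembled DNA insert (transcript-sense strand) plus feature table."""

    insert: NucleotideSequence
    features: tuple
    params_used: DesignParams
    target: str

    def feature_seq(self, f: Feature) -> NucleotideSequence:
        return NucleotideSequence(
            self.insert.residues[f.start : f.end], Alphabet.DNA
        )

    def features_of_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]

    def tiles_exactly(self) -> bool:
        """Features must cover the insert in order with no gaps or overlaps."""
        pos = 0
        for f in self.features:
            if f.start != pos or f.end <= f.start:
                return False
            pos = f.end
        return pos == len(self.insert)


_RNA_BASES = "ACGU"


def _nonpairing_bases(mirna_base: str) -> list:
    """Bases that neither WC- nor wobble-pair the given miRNA base."""
    return [
        b
        for b in _RNA_BASES
        if not is_wc(mirna_base, b) and not is_wobble(mirna_base, b)
    ]


def build_mbs(m: MiRNA, p: DesignParams, rng: Optional[random.Random] = None) -> MBS:
    """One binding site: reverse complement of the miRNA with bulge mismatches.

    MBS position q faces miRNA position L+1-q. Outside the bulge the MBS
    carries the Watson-Crick complement; at bulge positions the identity
    policy places the miRNA's own base (self-pairs are never WC nor
    wobble), while seeded_random draws uniformly from the non-pairing set.
    """
    p.validate_for(m)
    L = len(m)
    mir = m.seq.residues
    site = list(reverse_complement(m.seq).residues)
    if rng is None:
        rng = random.Random(p.rng_seed)
    mbs_positions = set()
    for mp in sorted(p.bulge_positions()):
        q = L + 1 - mp  # MBS position facing miRNA position mp
        mbs_positions.add(q)
        opposing = mir[mp - 1]
        if p.mismatch_policy is MismatchPolicy.IDENTITY:
            site[q - 1] = opposing
        else:
            site[q - 1] = rng.choice(_nonpairing_bases(opposing))
    return MBS(
        seq=NucleotideSequence("".join(site), Alphabet.RNA),
        bulge_positions_mbs=frozenset(mbs_positions),
        source_mirna=m.id,
    )


_SPACER_ATTEMPTS = 4096


def make_spacer(
    m: MiRNA,
    p: DesignParams,
    left_context: NucleotideSequence,
    right_context: NucleotideSequence,
    rng: random.Random,
) -> NucleotideSequence:
    """A spacer that creates no new target seed match and no forbidden site.

    Candidates of length ``spacer_len`` are drawn from the seeded RNG and
    rejected if, in the window left_context + spacer + right_context, any
    target seed match (6mer or better) or any forbidden restriction
    recognition sequence overlaps the spacer positions. The contexts are
    the adjacent MBS, so pre-existing sites wholly inside them are ignored.
    """
    if p.spacer_len == 0:
        return _EMPTY_RNA
    lo = len(left_context)
    hi = lo + p.spacer_len
    forbidden = set(p.forbidden_enzymes) | {p.flank5, p.flank3}
    for _ in range(_SPACER_ATTEMPTS):
        cand = "".join(rng.choice(_RNA_BASES) for _ in range(p.spacer_len))
        joined = NucleotideSequence(
            left_context.residues + cand + right_context.residues, Alphabet.RNA
        )
        if any(
            h.start < hi and h.end > lo for h in find_seed_matches(joined, m)
        ):
            continue
        dna = back_transcribe(joined)
        if any(
            start < hi and start + len(enz.recognition) > lo
            for enz, start in find_restriction_sites(dna, forbidden)
        ):
            continue
        return NucleotideSequence(cand, Alphabet.RNA)
    raise DesignError(
        f"no admissible {p.spacer_len}-nt spacer found in {_SPACER_ATTEMPTS} "
        "attempts; try a different rng_seed"
    )


class _EmptyRNA:
    """Stand-in for a zero-length spacer (NucleotideSequence forbids empty)."""

    residues = ""
    alphabet = Alphabet.RNA
    topology = Topology.LINEAR

    def __len__(self) -> int:
        return 0


_EMPTY_RNA = _EmptyRNA()


def assemble_insert(m: MiRNA, p: DesignParams = DesignParams()) -> SpongeConstruct:
    """Assemble flank5 + (MBS, spacer)*(n-1) + MBS + flank3 as sense-strand DNA.

    Spacers sit only between MBS, never outside the outermost ones. The
    whole assembly is deterministic for a fixed ``rng_seed``.
    """
    p.validate_for(m)
    rng = random.Random(p.rng_seed)
    mbs = build_mbs(m, p, rng)
    mbs_rna = mbs.seq.residues

    spacers = []
    left = mbs.seq
    right = mbs.seq
    if p.n_mbs > 1 and p.spacer_len > 0:
        if p.spacer_policy is SpacerPolicy.FIXED:
            one = make_spacer(m, p, left, right, random.Random(p.rng_seed))
            spacers = [one.residues] * (p.n_mbs - 1)
        else:
            spacers = [
                make_spacer(m, p, left, right, rng).residues
                for _ in range(p.n_mbs - 1)
            ]
    elif p.n_mbs > 1:
        spacers = [""] * (p.n_mbs - 1)

    parts = []
    features = []
    pos = 0

    def emit(name: str, kind: str, residues: str) -> None:
        nonlocal pos
        if residues:
            parts.append(residues)
            features.append(Feature(name, pos, pos + len(residues), kind))
            pos += len(residues)

    emit("flank5", "flank5", p.flank5.recognition.residues)
    for i in range(p.n_mbs):
        emit(f"MBS{i + 1}", "MBS", back_transcribe(mbs.seq).residues)
        if i < p.n_mbs - 1 and spacers and spacers[i]:
            emit(
                f"spacer{i + 1}",
                "spacer",
                spacers[i].replace("U", "T"),
            )
    emit("flank3", "flank3", p.flank3.recognition.residues)

    insert = NucleotideSequence("".join(parts), Alphabet.DNA)
    return SpongeConstruct(
        insert=insert, features=tuple(features), params_used=p, target=m.id
    )


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the in-silico construct checks; failures are entries, not errors."""

    target: str
    checks: tuple

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_tsv(self) -> str:
        lines = ["check\tpassed\tdetail"]
        lines += [f"{c.name}\t{c.passed}\t{c.detail}" for c in self.checks]
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "target": self.target,
                "passed": self.passed,
                "checks": [
                    {"name": c.name, "passed": c.passed, "detail": c.detail}
                    for c in self.checks
                ],
            },
            indent=2,
        )


def validate_construct(
    c: SpongeConstruct, m: MiRNA, decoys: Sequence = ()
) -> ValidationReport:
    """Run the full in-silico checklist against an assembled construct.

    Checks: (a) the scanner finds exactly n_mbs full target sites;
    (b) every MBS duplex pairs the seed perfectly and mismatches exactly
    the bulge window; (c) no forbidden recognition sequence occurs inside
    the insert (the two terminal flanks are exempt); (d) no decoy miRNA has
    a 7mer-or-better seed match anywhere in the transcript; (e) the feature
    table tiles the insert exactly.
    """
    p = c.params_used
    transcript = transcribe(c.insert)
    checks = []

    full = find_full_sites(transcript, m, p.bulge_window)
    checks.append(
        CheckResult(
            "site_count",
            len(full) == p.n_mbs,
            f"found {len(full)} full sites, expected {p.n_mbs}",
        )
    )

    bulge = p.bulge_positions()
    seed_lo, seed_hi = m.seed_range
    bad = []
    for f in c.features_of_kind("MBS"):
        rep = pair_duplex(m, transcribe(c.feature_seq(f)))
        seed_ok = all(
            rep.pairing[q - 1] == "|" for q in range(seed_lo, seed_hi + 1)
        )
        if not (seed_ok and rep.mismatch_positions() == bulge):
            bad.append(f.name)
    checks.append(
        CheckResult(
            "mbs_duplexes",
            not bad,
            "all MBS pair seed perfectly with bulge-only mismatches"
            if not bad
            else f"defective MBS: {', '.join(bad)}",
        )
    )

    forbidden = set(p.forbidden_enzymes) | {p.flank5, p.flank3}
    allowed_spans = {
        (f.start, f.end) for f in c.features if f.kind in ("flank5", "flank3")
    }
    internal = [
        (enz.name, start)
        for enz, start in find_restriction_sites(c.insert, forbidden)
        if (start, start + len(enz.recognition)) not in allowed_spans
    ]
    checks.append(
        CheckResult(
            "forbidden_sites",
            not internal,
            "no internal forbidden recognition sites"
            if not internal
            else "internal sites: "
            + ", ".join(f"{n}@{s}" for n, s in internal),
        )
    )

    strong = {SiteClass.SEVEN_MER_A1, SiteClass.SEVEN_MER_M8, SiteClass.EIGHT_MER}
    offenders = [
        d.id
        for d in decoys
        if any(h.site_class in strong for h in find_seed_matches(transcript, d))
    ]
    checks.append(
        CheckResult(
            "decoy_sites",
            not offenders,
            f"{len(decoys)} decoys, none with >=7mer matches"
            if not offenders
            else "decoys with >=7mer matches: " + ", ".join(offenders),
        )
    )

    checks.append(
        CheckResult(
            "feature_tiling",
            c.tiles_exactly(),
            "features tile the insert exactly"
            if c.tiles_exactly()
            else "feature table has gaps, overlaps, or wrong total length",
        )
    )

    return ValidationReport(target=m.id, checks=tuple(checks))
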