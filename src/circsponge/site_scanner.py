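"""Detect and classify miRNA binding sites and restriction sites.

Two families of hits are reported on linear or circular sequences:

* seed matches, using the canonical target-site taxonomy (6mer pairs
  miRNA positions 2-7; 7mer-m8 pairs 2-8; 7mer-A1 adds an A opposite
  position 1; 8mer is both). Seed classes require perfect Watson-Crick
  pairing over their defining window — G:U wobble counts as non-pairing.
* full-length sites: windows of miRNA length pairing perfectly everywhere
  except, optionally, inside a declared central bulge window (miRNA
  coordinates), classified ``full_perfect`` or ``full_bulged``.

Circular sequences are scanned with the doubled-sequence technique: hits
whose start lies in the first copy are kept, and a hit extending past the
origin is flagged ``spans_junction``. Overlapping hits are all reported;
deduplication is the caller's concern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .duplex_report import is_wc, wc_complement
from .seq_core import (
    Alphabet,
    MiRNA,
    NucleotideSequence,
    SequenceError,
    reverse_complement,
    transcribe,
)

__all__ = [
    "SiteClass",
    "BindingSite",
    "find_seed_matches",
    "find_full_sites",
    "find_restriction_sites",
    "hits_to_tsv",
    "hits_to_json",
]


class SiteClass(Enum):
    SIX_MER = "6mer"
    SEVEN_MER_A1 = "7mer-A1"
    SEVEN_MER_M8 = "7mer-m8"
    EIGHT_MER = "8mer"
    FULL_PERFECT = "full_perfect"
    FULL_BULGED = "full_bulged"


@dataclass(frozen=True)
class BindingSite:
    """One scanner hit, 0-based half-open on the canonical rotation."""

    mirna_id: str
    start: int
    end: int
    site_class: SiteClass
    mismatch_positions: frozenset = frozenset()
    spans_junction: bool = False

    def as_row(self, seq_id: str = ".") -> tuple:
        return (seq_id, self.start, self.end, self.site_class.value, self.mirna_id, "+")


def _as_rna(s: NucleotideSequence) -> NucleotideSequence:
    if s.alphabet is Alphabet.DNA:
        return transcribe(s)
    return s


def _scan_text(s: NucleotideSequence) -> tuple:
    """(text, n_starts, wrap) — doubled text for circular inputs."""
    res = s.residues
    if s.is_circular:
        return res + res, len(res), True
    return res, len(res), False


def find_seed_matches(s: NucleotideSequence, m: MiRNA) -> list:
    """All seed-complementary sites of ``m`` in ``s``, best class per core.

    A hit is anchored at a 6-nt core pairing miRNA positions 2-7 and
    extended to 7mer-m8 (base 5' of the core pairs position 8) and/or
    7mer-A1 (an A immediately 3' of the core, opposite position 1). Each
    core is reported once with its largest class; the reported interval is
    the matched window of that class.
    """
    s = _as_rna(s)
    text, n_starts, wrap = _scan_text(s)
    L = len(s)
    mir = m.seq.residues
    if len(mir) < 8:
        raise SequenceError("miRNA shorter than the 8-nt seed region")
    # 5'->3' site core complementary to miRNA 2..7 (antiparallel).
    core = "".join(wc_complement(b) for b in mir[1:7])[::-1]
    m8_base = wc_complement(mir[7])
    hits = []
    i = text.find(core)
    while i != -1 and i < n_starts:
        has_m8 = i - 1 >= 0 and text[i - 1] == m8_base
        if wrap and i == 0:
            has_m8 = text[L - 1] == m8_base
        has_a1 = i + 6 < len(text) and text[i + 6] == "A"
        if has_m8 and has_a1:
            cls, lo, hi = SiteClass.EIGHT_MER, i - 1, i + 7
        elif has_m8:
            cls, lo, hi = SiteClass.SEVEN_MER_M8, i - 1, i + 6
        elif has_a1:
            cls, lo, hi = SiteClass.SEVEN_MER_A1, i, i + 7
        else:
            cls, lo, hi = SiteClass.SIX_MER, i, i + 6
        if wrap and i == 0 and has_m8:
            lo = L - 1  # m8 base sits just before the origin
            spans = True
            start = lo
            end = (hi % L) or L
        else:
            spans = wrap and hi > L
            start = lo % L if wrap else lo
            end = hi % L if (wrap and hi > L) else hi
        hits.append(
            BindingSite(m.id, start, end, cls, frozenset(), spans_junction=spans)
        )
        i = text.find(core, i + 1)
    return hits


def find_full_sites(
    s: NucleotideSequence, m: MiRNA, bulge_window: Optional[tuple] = None
) -> list:
    """Full-length (miRNA-sized) sites, perfect or centrally bulged.

    A window qualifies if every miRNA position pairs Watson-Crick except
    positions inside ``bulge_window`` (1-based inclusive, miRNA
    coordinates), which may mismatch. Zero mismatches -> ``full_perfect``;
    otherwise ``full_bulged`` with the mismatched miRNA positions reported.
    With ``bulge_window=None`` only perfect sites are found.
    """
    s = _as_rna(s)
    text, n_starts, wrap = _scan_text(s)
    L = len(m)
    mir = m.seq.residues
    allowed = (
        set(range(bulge_window[0], bulge_window[1] + 1)) if bulge_window else set()
    )
    hits = []
    limit = len(text) - L + 1 if not wrap else min(n_starts, len(text) - L + 1)
    for i in range(max(limit, 0)):
        window = text[i : i + L]
        mism = []
        ok = True
        for p in range(1, L + 1):
            if not is_wc(mir[p - 1], window[L - p]):
                if p in allowed:
                    mism.append(p)
                else:
                    ok = False
                    break
        if not ok:
            continue
        cls = SiteClass.FULL_PERFECT if not mism else SiteClass.FULL_BULGED
        end = i + L
        spans = wrap and end > n_starts
        hits.append(
            BindingSite(
                m.id,
                i,
                end % n_starts if spans else end,
                cls,
                frozenset(mism),
                spans_junction=spans,
            )
        )
    return hits


def find_restriction_sites(s: NucleotideSequence, enzymes: Iterable) -> list:
    """Every recognition-sequence occurrence, as (enzyme, 0-based start).

    The sense strand is scanned; for non-palindromic enzymes the antisense
    strand is covered by additionally searching the reverse complement of
    the recognition sequence. Circular inputs are scanned across the
    junction. Results are sorted by start position.
    """
    if s.alphabet is not Alphabet.DNA:
        raise SequenceError("restriction scanning expects DNA input")
    text, n_starts, wrap = _scan_text(s)
    out = []
    for enz in enzymes:
        patterns = {enz.recognition.residues}
        rc = reverse_complement(
            NucleotideSequence(enz.recognition.residues, Alphabet.DNA)
        ).residues
        patterns.add(rc)  # set: collapses for palindromes
        for pat in patterns:
            i = text.find(pat)
            while i != -1 and i < n_starts:
                if not wrap or i + len(pat) <= 2 * n_starts:
                    out.append((enz, i))
                i = text.find(pat, i + 1)
    out.sort(key=lambda t: (t[1], t[0].name))
    return out


def hits_to_tsv(hits: Iterable, seq_id: str = ".") -> str:
    """BED-like TSV: seq id, start, end, class, miRNA id, strand."""
    lines = ["\t".join(map(str, h.as_row(seq_id))) for h in hits]
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_json(hits: Iterable, seq_id: str = ".") -> str:
    return json.dumps(
        [
            {
                "seq_id": seq_id,
                "mirna_id": h.mirna_id,
                "start": h.start,
                "end": h.end,
                "class": h.site_class.value,
                "mismatch_positions": sorted(h.mismatch_positions),
                "spans_junction": h.spans_junction,
            }
            for h in hits
        ],
        indent=2,
    )
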