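"""Read/write designed constructs as GenBank flat files and FASTA.

GenBank carries the feature table (flank5, MBS1..MBSn, spacer1.., flank3)
as ``misc_feature`` entries with 1-based inclusive locations, plus a
key=value metadata block (design parameters, seed, tool version) in the
COMMENT field that round-trips exactly. The LOCUS line uses "DNA linear"
for inserts and "RNA circular" for transcripts so downstream viewers
render topology correctly.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .seq_core import Alphabet, NucleotideSequence, Topology
from .sponge_design import Feature, SpongeConstruct

__all__ = [
    "AnnotatedRecord",
    "GenBankParseError",
    "record_from_construct",
    "write_genbank",
    "read_genbank",
    "write_fasta",
    "read_fasta",
]

_META_PREFIX = "circsponge-meta:"


class GenBankParseError(ValueError):
    """Malformed GenBank flat file; carries a best-effort line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


@dataclass(frozen=True)
class AnnotatedRecord:
    """A sequence with an ordered feature table and free-form metadata."""

    id: str
    sequence: NucleotideSequence
    features: tuple = ()
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < f.end <= n):
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}) outside sequence of length {n}"
                )


def record_from_construct(
    c: SpongeConstruct, id: str = None, extra_metadata: Mapping = None
) -> AnnotatedRecord:
    """Snapshot a construct (sequence, features, design params) for output."""
    p = c.params_used
    meta = {
        "target": c.target,
        "n_mbs": str(p.n_mbs),
        "bulge_window": f"{p.bulge_window[0]}-{p.bulge_window[1]}"
        if p.bulge_window
        else "none",
        "spacer_len": str(p.spacer_len),
        "flank5": p.flank5.name,
        "flank3": p.flank3.name,
        "forbidden": ",".join(sorted(e.name for e in p.forbidden_enzymes)),
        "mismatch_policy": p.mismatch_policy.value,
        "spacer_policy": p.spacer_policy.value,
        "rng_seed": str(p.rng_seed),
    }
    if extra_metadata:
        meta.update({k: str(v) for k, v in extra_metadata.items()})
    return AnnotatedRecord(
        id=id or f"{c.target}_sponge",
        sequence=c.insert,
        features=tuple(c.features),
        metadata=meta,
    )


def _locus_name(id: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", id)[:16] or "record"


def _to_seqrecord(r: AnnotatedRecord) -> SeqRecord:
    rec = SeqRecord(Seq(r.sequence.residues), id=r.id, name=_locus_name(r.id))
    rec.description = ""
    rec.annotations["molecule_type"] = r.sequence.alphabet.value
    rec.annotations["topology"] = (
        "circular" if r.sequence.is_circular else "linear"
    )
    if r.metadata:
        rec.annotations["comment"] = "\n".join(
            f"{_META_PREFIX} {k}={v}" for k, v in r.metadata.items()
        )
    for f in r.features:
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end),
                type="misc_feature",
                qualifiers={"label": [f.name], "note": [f"kind={f.kind}"]},
            )
        )
    return rec


def write_genbank(r: AnnotatedRecord) -> str:
    """GenBank flat-file text; read(write(r)) reproduces r exactly."""
    handle = io.StringIO()
    SeqIO.write([_to_seqrecord(r)], handle, "genbank")
    return handle.getvalue()


def read_genbank(text: str) -> AnnotatedRecord:
    """Parse one GenBank record back into an :class:`AnnotatedRecord`."""
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except ValueError as exc:
        line = None
        msg = str(exc)
        hit = re.search(r"line (\d+)", msg)
        if hit:
            line = int(hit.group(1))
        raise GenBankParseError(f"cannot parse GenBank text: {msg}", line) from exc
    mol = rec.annotations.get("molecule_type", "DNA")
    alphabet = Alphabet.RNA if "RNA" in mol.upper() else Alphabet.DNA
    topology = (
        Topology.CIRCULAR
        if rec.annotations.get("topology") == "circular"
        else Topology.LINEAR
    )
    seq = NucleotideSequence(str(rec.seq), alphabet, topology)
    features = []
    for f in rec.features:
        if f.type != "misc_feature":
            continue
        name = (f.qualifiers.get("label") or ["feature"])[0]
        kind = "misc"
        for note in f.qualifiers.get("note", []):
            if note.startswith("kind="):
                kind = note[len("kind=") :]
        features.append(
            Feature(name, int(f.location.start), int(f.location.end), kind)
        )
    metadata = {}
    comment = rec.annotations.get("comment", "")
    for line in comment.splitlines():
        line = line.strip()
        if line.startswith(_META_PREFIX):
            body = line[len(_META_PREFIX) :].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                metadata[k] = v
    return AnnotatedRecord(
        id=rec.id, sequence=seq, features=tuple(features), metadata=metadata
    )


def write_fasta(records: Iterable[AnnotatedRecord]) -> str:
    """Standard FASTA, 60-column wrap; circular topology noted in the description."""
    seen = set()
    lines = []
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
        desc = " topology=circular" if r.sequence.is_circular else ""
        lines.append(f">{r.id}{desc}")
        res = r.sequence.residues
        lines.extend(res[i : i + 60] for i in range(0, len(res), 60))
    return "\n".join(lines) + ("\n" if lines else "")


def read_fasta(text: str) -> list:
    """Parse FASTA text; alphabet inferred (U -> RNA, otherwise DNA)."""
    records = []
    seen = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        alphabet = Alphabet.RNA if "U" in residues else Alphabet.DNA
        topology = (
            Topology.CIRCULAR
            if "topology=circular" in rec.description
            else Topology.LINEAR
        )
        records.append(
            AnnotatedRecord(
                id=rec.id,
                sequence=NucleotideSequence(residues, alphabet, topology),
            )
        )
    return records
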