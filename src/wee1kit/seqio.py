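"""Protein sequence and alignment I/O.

Sequences are plain protein strings over the 20 standard residues plus ``X``
(unknown); alignments additionally allow the gap character ``-``. Parsing of
the container formats (FASTA, Clustal) is delegated to Biopython; this module
owns validation, header conventions and the domain types used by the rest of
the package.

Header convention: ``>id [species=...] [accession=...] free text``. The first
whitespace-delimited token is the record id; optional ``key=value`` bracket
tags carry species and accession; the full header is kept as the description.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}
GAP = "-"

PathOrStream = Union[str, Path, TextIO]


class SequenceError(ValueError):
    """Malformed sequence input (bad residue, duplicate id, ragged alignment...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence.

    ``residues`` is uppercase over the 20 standard amino acids plus ``X``.
    """

    id: str
    residues: str
    species: str = ""
    accession: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in ALPHABET:
                raise SequenceError(
                    f"record {self.id!r}: invalid residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRecord:
    """A gapped row of an alignment; degapping recovers the input sequence."""

    id: str
    residues: str
    species: str = ""
    accession: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty aligned row")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in ALPHABET and aa != GAP:
                raise SequenceError(
                    f"record {self.id!r}: invalid symbol {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def degap(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            species=self.species,
            accession=self.accession,
            description=self.description,
        )


def _check_unique_ids(records: Iterable) -> None:
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


_TAG_RE = re.compile(r"\[(species|accession)=([^\]]*)\]")


def _parse_header(header_id: str, description: str) -> dict:
    tags = dict(_TAG_RE.findall(description))
    return {
        "id": header_id,
        "species": tags.get("species", ""),
        "accession": tags.get("accession", ""),
        "description": description,
    }


def _normalize_residues(rec_id: str, raw: str, allow_gap: bool) -> str:
    seq = raw.upper()
    if seq.endswith("*"):  # terminal stop from translated CDS
        seq = seq[:-1]
    allowed = ALPHABET | ({GAP} if allow_gap else set())
    for pos, aa in enumerate(seq, start=1):
        if aa not in allowed:
            raise SequenceError(
                f"record {rec_id!r}: invalid residue {aa!r} at position {pos}"
            )
    return seq


def _as_handle(source: PathOrStream, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def read_fasta(source: PathOrStream) -> list[SequenceRecord]:
    """Read protein FASTA into validated :class:`SequenceRecord` objects.

    Lowercase residues are uppercased, a single trailing ``*`` is stripped,
    and any symbol outside the amino-acid alphabet (including ``.`` and
    digits) raises :class:`SequenceError` naming the offending position.
    """
    handle, owned = _as_handle(source)
    try:
        raw = list(SeqIO.parse(handle, "fasta"))
    finally:
        if owned:
            handle.close()
    if not raw:
        raise SequenceError("no FASTA records found (empty input?)")
    records = []
    for sr in raw:
        meta = _parse_header(sr.id, sr.description)
        records.append(
            SequenceRecord(
                residues=_normalize_residues(sr.id, str(sr.seq), allow_gap=False),
                **meta,
            )
        )
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable, dest: PathOrStream, width: int = 60) -> None:
    """Write records (gapped or ungapped) as FASTA with ``width`` residues/line."""
    if width < 1:
        raise ValueError(f"line width must be >= 1, got {width}")
    records = list(records)
    _check_unique_ids(records)
    handle, owned = _as_handle(dest, "w")
    try:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            handle.write(f">{header}\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start : start + width] + "\n")
    finally:
        if owned:
            handle.close()


def fasta_str(records: Iterable, width: int = 60) -> str:
    buf = io.StringIO()
    write_fasta(records, buf, width=width)
    return buf.getvalue()


def read_alignment(source: PathOrStream, dialect: str = "aligned-fasta") -> list[AlignedRecord]:
    """Read an alignment as equal-length gapped records.

    ``dialect`` is ``"aligned-fasta"`` or ``"clustal"``. Clustal conservation
    lines are ignored by the parser. Ragged rows raise :class:`SequenceError`
    naming the offending id.
    """
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    handle, owned = _as_handle(source)
    try:
        if fmt == "fasta":
            raw = list(SeqIO.parse(handle, "fasta"))
        else:
            raw = list(AlignIO.read(handle, "clustal"))
    finally:
        if owned:
            handle.close()
    if not raw:
        raise SequenceError("no alignment records found (empty input?)")
    records = []
    for sr in raw:
        meta = _parse_header(sr.id, sr.description)
        records.append(
            AlignedRecord(
                residues=_normalize_residues(sr.id, str(sr.seq), allow_gap=True),
                **meta,
            )
        )
    _check_unique_ids(records)
    length = len(records[0])
    for rec in records:
        if len(rec) != length:
            raise SequenceError(
                f"ragged alignment: record {rec.id!r} has length "
                f"{len(rec)}, expected {length}"
            )
    return records
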