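"""Reference-anchored residue numbering.

Conservation figures for kinase families are conventionally numbered by one
reference sequence (here human WEE1A): every other sequence's residues are
reported by the reference position they align to. This module builds the
column <-> reference-position map for an alignment, answers "what does
sequence S carry at reference position P (and at which of its own
positions)?", and extracts reference-delimited segments such as the G-loop or
the activation segment.

Two modes cover the two ways such numbers are produced in practice: from a
full multiple alignment, or from a pairwise global alignment of one sequence
against the reference (``pairwise_column_map``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .msa import MultipleAlignment
from .pairwise import PairwiseAlignment, ScoringScheme, global_align
from .seqio import GAP, SequenceRecord


class AnchorError(ValueError):
    pass


@dataclass(frozen=True)
class Observation:
    """What one sequence shows at a reference position.

    ``residue`` is a residue letter or '-'; ``own_position`` is that
    sequence's 1-based ungapped position (None when gapped);
    ``in_alignment`` is False when the reference position falls outside the
    (possibly trimmed) alignment.
    """

    seq_id: str
    ref_pos: int
    residue: str
    own_position: Optional[int]
    in_alignment: bool = True


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional map between alignment columns and reference numbering.

    ``col_to_refpos[c]`` is the 1-based reference residue number carried by
    column ``c`` (0-based), or None where the reference row is gapped.
    ``ref_offset`` supports alignments that cover only part of the reference
    (e.g. after end trimming): numbering still refers to the full-length
    reference.
    """

    ref_id: str
    col_to_refpos: tuple
    refpos_to_col: dict

    def column_for(self, ref_pos: int) -> Optional[int]:
        return self.refpos_to_col.get(ref_pos)

    @property
    def ref_positions(self) -> range:
        if not self.refpos_to_col:
            raise AnchorError("reference row is all gaps")
        return range(min(self.refpos_to_col), max(self.refpos_to_col) + 1)


def build_column_map(msa: MultipleAlignment, ref_id: str,
                     ref_start: int = 1) -> ColumnMap:
    """Number alignment columns by the reference row.

    ``ref_start`` is the reference number of the reference row's first
    residue (1 for a full-length reference; larger if the aligned reference
    is itself a fragment).
    """
    try:
        ref_row = msa.row(ref_id)
    except KeyError:
        raise AnchorError(f"reference id {ref_id!r} not in alignment") from None
    col_to_refpos: list[Optional[int]] = []
    refpos_to_col: dict[int, int] = {}
    pos = ref_start - 1
    for c, aa in enumerate(ref_row.residues):
        if aa == GAP:
            col_to_refpos.append(None)
        else:
            pos += 1
            col_to_refpos.append(pos)
            refpos_to_col[pos] = c
    if not refpos_to_col:
        raise AnchorError(f"reference row {ref_id!r} contains no residues")
    return ColumnMap(ref_id=ref_id, col_to_refpos=tuple(col_to_refpos),
                     refpos_to_col=refpos_to_col)


def pairwise_column_map(reference: SequenceRecord, query: SequenceRecord,
                        scheme: ScoringScheme | None = None
                        ) -> tuple[MultipleAlignment, ColumnMap]:
    """Align one query globally to the reference and anchor the result.

    This is the mode behind per-species position reports like "the residue
    homologous to human E309 sits at Arabidopsis position 259".
    """
    aln = global_align(reference, query, scheme)
    msa = MultipleAlignment(records=(aln.a, aln.b))
    return msa, build_column_map(msa, reference.id)


def residue_at(msa: MultipleAlignment, cmap: ColumnMap, seq_id: str,
               ref_pos: int) -> Observation:
    """The ``seq_id`` row's symbol in the column carrying ``ref_pos``.

    When the position was trimmed out of the alignment the result is an
    explicit out-of-alignment observation, not an exception.
    """
    row = msa.row(seq_id)  # KeyError on unknown id
    col = cmap.column_for(ref_pos)
    if col is None:
        lo, hi = min(cmap.refpos_to_col), max(cmap.refpos_to_col)
        if ref_pos < lo or ref_pos > hi:
            return Observation(seq_id=seq_id, ref_pos=ref_pos, residue=GAP,
                              own_position=None, in_alignment=False)
        raise AnchorError(
            f"reference position {ref_pos} is gapped in the reference row"
        )
    aa = row.residues[col]
    if aa == GAP:
        return Observation(seq_id=seq_id, ref_pos=ref_pos, residue=GAP,
                           own_position=None)
    own = sum(1 for ch in row.residues[: col + 1] if ch != GAP)
    return Observation(seq_id=seq_id, ref_pos=ref_pos, residue=aa,
                       own_position=own)


def extract_segment(msa: MultipleAlignment, cmap: ColumnMap,
                    ref_start: int, ref_end: int) -> MultipleAlignment:
    """Columns spanning reference positions ``ref_start..ref_end`` inclusive.

    Reference-gap columns inside the span are retained. Raises on positions
    outside the reference coverage of the alignment.
    """
    if ref_start > ref_end:
        raise AnchorError("ref_start must be <= ref_end")
    c0 = cmap.column_for(ref_start)
    c1 = cmap.column_for(ref_end)
    if c0 is None or c1 is None:
        raise AnchorError(
            f"segment {ref_start}..{ref_end} is outside the aligned reference"
        )
    from .seqio import AlignedRecord

    out = tuple(
        AlignedRecord(id=r.id, residues=r.residues[c0 : c1 + 1],
                      species=r.species, accession=r.accession,
                      description=r.description)
        for r in msa.records
    )
    return MultipleAlignment(records=out)
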