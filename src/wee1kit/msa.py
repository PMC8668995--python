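"""Progressive multiple sequence alignment and end trimming.

A Clustal-style single-pass progressive aligner: pairwise p-distances feed a
neighbor-joining guide tree (midpoint rooted), and profiles are merged in
post-order with profile-profile scores given by the frequency-weighted average
substitution score and the same affine gap penalties as the pairwise stage.
Alignment never edits residues, so degapping any row recovers its input.

End trimming removes the ragged leading/trailing columns where incomplete
sequences leave the alignment sparsely occupied; interior columns are never
touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phylo
from .pairwise import (
    _ALPHA,
    _INDEX,
    ScoringScheme,
    align_score_grid,
    blosum62,
    global_align,
)
from .seqio import GAP, AlignedRecord, SequenceRecord, SequenceError


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows with no all-gap column."""

    records: tuple

    def __post_init__(self) -> None:
        recs = tuple(self.records)
        object.__setattr__(self, "records", recs)
        if not recs:
            raise SequenceError("alignment has no rows")
        length = len(recs[0])
        for rec in recs:
            if len(rec) != length:
                raise SequenceError(
                    f"ragged alignment: {rec.id!r} has length {len(rec)}, "
                    f"expected {length}"
                )
        ids = [r.id for r in recs]
        if len(set(ids)) != len(ids):
            raise SequenceError("duplicate ids in alignment")
        for col in range(length):
            if all(r.residues[col] == GAP for r in recs):
                raise SequenceError(f"column {col + 1} is gap in every row")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, seq_id: str) -> AlignedRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"no row with id {seq_id!r}")

    def column(self, index: int) -> str:
        return "".join(r.residues[index] for r in self.records)


def distance_matrix(records: list[SequenceRecord],
                    scheme: ScoringScheme | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise p-distances in input order."""
    if len(records) < 2:
        raise SequenceError("need at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate sequence ids")
    if scheme is None:
        scheme = blosum62()
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], scheme)
            d = 1.0 - aln.identity_pct / 100.0
            D[i, j] = D[j, i] = d
    return D


# A profile is (ids, rows): parallel lists of row ids and gapped strings.
_GAPIDX = 21  # frequency-vector slot for the gap symbol; scores zero


def _profile_freqs(rows: list[str]) -> np.ndarray:
    ncol = len(rows[0])
    F = np.zeros((ncol, 22))
    for row in rows:
        for c, aa in enumerate(row):
            F[c, _GAPIDX if aa == GAP else _INDEX[aa]] += 1.0
    return F / len(rows)


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    scheme: ScoringScheme) -> tuple[list[str], list[str]]:
    S = np.zeros((22, 22))
    S[:21, :21] = scheme.matrix
    FA = _profile_freqs(rows_a)
    FB = _profile_freqs(rows_b)
    grid = FA @ S @ FB.T
    _, ops = align_score_grid(grid, scheme.gap_open, scheme.gap_extend)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op in ("M", "Y"):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
        if op in ("M", "X"):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
            j += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_align(records: list[SequenceRecord],
                      scheme: ScoringScheme | None = None) -> MultipleAlignment:
    """Guide-tree progressive alignment.

    The guide tree is neighbor joining on p-distances, midpoint rooted; leaves
    are merged bottom-up with children visited in order of their smallest
    member id, so the result is deterministic.
    """
    if scheme is None:
        scheme = blosum62()
    if len(records) < 2:
        raise SequenceError("need at least 2 sequences to align")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise SequenceError("duplicate sequence ids")

    if len(records) == 2:
        aln = global_align(records[0], records[1], scheme)
        return MultipleAlignment(records=(aln.a, aln.b))

    D = distance_matrix(records, scheme)
    guide = phylo.midpoint_root(
        phylo.neighbor_joining(D, [r.id for r in records])
    )

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [by_id[node.label].residues]
        parts = [merge(c) for c in node.children]
        parts.sort(key=lambda p: min(p[0]))
        ids, rows = parts[0]
        for nxt_ids, nxt_rows in parts[1:]:
            rows, nxt_rows = _merge_profiles(rows, nxt_rows, scheme)
            ids = ids + nxt_ids
            rows = rows + nxt_rows
        return ids, rows

    ids, rows = merge(guide.root)
    out = []
    for rid, row in zip(ids, rows):
        src = by_id[rid]
        out.append(AlignedRecord(id=rid, residues=row, species=src.species,
                                 accession=src.accession,
                                 description=src.description))
    # restore input order
    order = {r.id: k for k, r in enumerate(records)}
    out.sort(key=lambda r: order[r.id])
    return MultipleAlignment(records=tuple(out))


def column_occupancy(msa: MultipleAlignment) -> np.ndarray:
    """Per-column fraction of non-gap rows."""
    n = len(msa.records)
    return np.array(
        [sum(r.residues[c] != GAP for r in msa.records) / n
         for c in range(msa.n_columns)]
    )


def trim_bounds(msa: MultipleAlignment, min_occupancy: float) -> tuple[int, int]:
    """Column slice [lo, hi) kept by :func:`trim_ends` at this occupancy."""
    if not 0.0 < min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be in (0, 1]")
    occ = column_occupancy(msa)
    lo = 0
    while lo < len(occ) and occ[lo] < min_occupancy:
        lo += 1
    hi = len(occ)
    while hi > lo and occ[hi - 1] < min_occupancy:
        hi -= 1
    if lo >= hi:
        raise SequenceError(
            f"trimming at occupancy {min_occupancy} removes the whole alignment"
        )
    return lo, hi


def trim_ends(msa: MultipleAlignment, min_occupancy: float = 0.5) -> MultipleAlignment:
    """Truncate ragged alignment ends.

    Removes the maximal prefix and suffix runs of columns whose non-gap
    fraction is below ``min_occupancy``. Interior columns are untouched, so
    the operation is idempotent. Trimming away every column is an error.
    """
    lo, hi = trim_bounds(msa, min_occupancy)
    if lo == 0 and hi == msa.n_columns:
        return msa
    out = tuple(
        AlignedRecord(id=r.id, residues=r.residues[lo:hi], species=r.species,
                      accession=r.accession, description=r.description)
        for r in msa.records
    )
    return MultipleAlignment(records=out)
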