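"""Global pairwise alignment with affine gap penalties.

Needleman-Wunsch / Gotoh dynamic programming over protein sequences. A gap of
length ``k`` costs ``gap_open + k * gap_extend``; end gaps are penalized (true
global alignment). The traceback is deterministic, preferring diagonal over
up over left moves on score ties, so identical inputs always yield identical
alignments.

The default scoring scheme is BLOSUM62 with gap open 10 and extend 0.5,
a Clustal-like parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMINO_ACIDS, GAP, AlignedRecord, SequenceRecord

# residue -> index; X is index 20 and scores 0 against everything
_ALPHA = AMINO_ACIDS + "X"
_INDEX = {aa: i for i, aa in enumerate(_ALPHA)}

_TOL = 1e-9  # scores are sums of matrix entries and gap multiples; ties are exact


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Symmetric 21x21 substitution scores (X row/col zero) plus affine gap costs."""

    matrix: np.ndarray
    gap_open: float = 10.0
    gap_extend: float = 0.5
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (21, 21):
            raise ValueError(f"substitution matrix must be 21x21, got {m.shape}")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        object.__setattr__(self, "matrix", m)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_INDEX[a], _INDEX[b]])

    @staticmethod
    def from_ncbi_file(path: str | Path, gap_open: float = 10.0,
                       gap_extend: float = 0.5) -> "ScoringScheme":
        """Load an NCBI-format substitution matrix text file."""
        arr = substitution_matrices.read(str(path))
        return ScoringScheme(_embed_biopython_matrix(arr), gap_open, gap_extend,
                             name=Path(path).stem)


def _embed_biopython_matrix(arr) -> np.ndarray:
    m = np.zeros((21, 21))
    letters = arr.alphabet
    for i, a in enumerate(letters):
        if a not in _INDEX or a == "X":
            continue
        for j, b in enumerate(letters):
            if b not in _INDEX or b == "X":
                continue
            m[_INDEX[a], _INDEX[b]] = arr[i, j]
    return m


@lru_cache(maxsize=None)
def blosum62(gap_open: float = 10.0, gap_extend: float = 0.5) -> ScoringScheme:
    """The default scheme: BLOSUM62, open 10, extend 0.5."""
    arr = substitution_matrices.load("BLOSUM62")
    return ScoringScheme(_embed_biopython_matrix(arr), gap_open, gap_extend,
                         name="BLOSUM62")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows, the optimal score, and percent identity."""

    a: AlignedRecord
    b: AlignedRecord
    score: float
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise AlignmentError("aligned rows differ in length")
        for ca, cb in zip(self.a.residues, self.b.residues):
            if ca == GAP and cb == GAP:
                raise AlignmentError("column gapped in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.a)


def percent_identity(row_a: str, row_b: str) -> float:
    """100 x identical columns / co-aligned (both non-gap) columns; 0 if none."""
    both = [(x, y) for x, y in zip(row_a, row_b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    matches = sum(x == y for x, y in both)
    return 100.0 * matches / len(both)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_INDEX[aa] for aa in seq), dtype=np.intp, count=len(seq))


def _gotoh_matrices(sub: np.ndarray, open_cost: float, ext: float):
    """Fill the three Gotoh state matrices for a (n x m) substitution score grid.

    States: M (residues aligned), Y (gap in the column sequence: vertical/up
    move consuming a row residue), X (gap in the row sequence: horizontal/left
    move consuming a column residue). Opening a gap costs open+extend for its
    first position.
    """
    n, m = sub.shape
    NEG = -np.inf
    M = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    X[0, 1:] = -(open_cost + j * ext)
    i = np.arange(1, n + 1)
    Y[1:, 0] = -(open_cost + i * ext)

    first = open_cost + ext
    jm = np.arange(m + 1)
    for r in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[r - 1], Y[r - 1]), X[r - 1])
        M[r, 1:] = sub[r - 1] + prev_best[:-1]
        Y[r, 1:] = np.maximum(
            np.maximum(M[r - 1, 1:], X[r - 1, 1:]) - first,
            Y[r - 1, 1:] - ext,
        )
        # X depends on this row to the left: running max over gap starts
        B = np.maximum(M[r], Y[r])  # gap can open after a match or a vertical gap
        A = np.where(np.isfinite(B), B + jm * ext, NEG)
        run = np.maximum.accumulate(A)
        X[r, 1:] = run[:-1] - first - (jm[1:] - 1) * ext
        X[r, 1:] = np.maximum(X[r, 1:], NEG)
    return M, Y, X


def align_score_grid(sub: np.ndarray, gap_open: float, gap_extend: float):
    """Optimal global alignment over an arbitrary (n x m) position-score grid.

    Returns ``(score, ops)`` where ops is a list of moves from the start:
    'M' consumes one row and one column position, 'Y' one row (gap on the
    column side), 'X' one column (gap on the row side). This is the shared
    engine for residue-residue and profile-profile alignment.
    """
    M, Y, X = _gotoh_matrices(np.asarray(sub, dtype=float), gap_open, gap_extend)
    return _traceback(sub.shape[0], sub.shape[1], M, Y, X, gap_open, gap_extend)


def _traceback(n: int, m: int, M, Y, X, open_cost: float, ext: float):
    first = open_cost + ext
    # final state: prefer M (diagonal) > Y (up) > X (left) on ties
    finals = [("M", M[n, m]), ("Y", Y[n, m]), ("X", X[n, m])]
    best = max(v for _, v in finals)
    state = next(s for s, v in finals if v >= best - _TOL)

    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        ops.append(state)
        if state == "M":
            prev = max(M[i - 1, j - 1], Y[i - 1, j - 1], X[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, v in (("M", M[i, j]), ("Y", Y[i, j]), ("X", X[i, j])):
                if v >= prev - _TOL:
                    state = s
                    break
        elif state == "Y":  # up: consume a row position, gap on the column side
            val = Y[i, j]
            i -= 1
            if abs(M[i, j] - first - val) <= _TOL:
                state = "M"
            elif abs(Y[i, j] - ext - val) <= _TOL:
                state = "Y"
            elif abs(X[i, j] - first - val) <= _TOL:
                state = "X"
            elif i == 0:
                state = "Y"  # leading gap column run
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed in state Y")
        else:  # X, left: consume a column position, gap on the row side
            val = X[i, j]
            j -= 1
            if j > 0 or i > 0:
                if abs(M[i, j] - first - val) <= _TOL:
                    state = "M"
                elif abs(Y[i, j] - first - val) <= _TOL:
                    state = "Y"
                elif abs(X[i, j] - ext - val) <= _TOL:
                    state = "X"
                elif i == 0:
                    state = "X"
                else:  # pragma: no cover - defensive
                    raise AssertionError("traceback failed in state X")
        if i == 0 and j == 0:
            break
    ops.reverse()
    return float(best), ops


def _apply_ops(seq1: str, seq2: str, ops: list[str]) -> tuple[str, str]:
    out1, out2 = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            out1.append(seq1[i]); out2.append(seq2[j]); i += 1; j += 1
        elif op == "Y":
            out1.append(seq1[i]); out2.append(GAP); i += 1
        else:
            out1.append(GAP); out2.append(seq2[j]); j += 1
    return "".join(out1), "".join(out2)


def global_align(s1: SequenceRecord, s2: SequenceRecord,
                 scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Returns the alignment maximizing the substitution score minus affine gap
    costs (``gap_open + k*gap_extend`` for a length-``k`` gap, end gaps
    included). Ties are resolved deterministically (diagonal > up > left).
    """
    if scheme is None:
        scheme = blosum62()
    if not s1.residues or not s2.residues:
        raise AlignmentError("cannot align an empty sequence")
    e1, e2 = _encode(s1.residues), _encode(s2.residues)
    sub = scheme.matrix[np.ix_(e1, e2)]
    score, ops = align_score_grid(sub, scheme.gap_open, scheme.gap_extend)
    row1, row2 = _apply_ops(s1.residues, s2.residues, ops)
    a = AlignedRecord(id=s1.id, residues=row1, species=s1.species,
                      accession=s1.accession, description=s1.description)
    b = AlignedRecord(id=s2.id, residues=row2, species=s2.species,
                      accession=s2.accession, description=s2.description)
    return PairwiseAlignment(a=a, b=b, score=float(score),
                             identity_pct=percent_identity(row1, row2))


def p_distance(s1: SequenceRecord, s2: SequenceRecord,
               scheme: ScoringScheme | None = None) -> float:
    """1 - fractional identity of the optimal global alignment; in [0, 1]."""
    aln = global_align(s1, s2, scheme)
    return 1.0 - aln.identity_pct / 100.0
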