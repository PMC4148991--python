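"""Affine-gap Needleman-Wunsch global alignment and identity statistics.

This is the aligner behind the AGIOS statistic: a true global alignment
(end gaps penalized) under three-state affine-gap dynamic programming
(match state M, gap-in-b state Ix, gap-in-a state Iy). A gap of length L
costs ``gap_open + L * gap_extend``. Traceback is deterministic: on
ties, diagonal beats up (gap in b) beats left (gap in a), and within a
state the predecessor preference is M > Ix > Iy.

Percent identity counts matches over ALL alignment columns, including
internal and terminal gap columns, which is the most conservative
convention; ``percent_identity(..., include_terminal_gaps=False)``
reports the alternative that drops terminal gap runs from the
denominator. Ambiguous residues (N and the other IUPAC codes; X for
proteins) never count as matches.

The inner loops are jit-compiled with numba; the algorithm itself is
implemented here in full and is oracle-verified in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from agios.seqio import SequenceRecord

NUCLEOTIDE_ORDER = "ACGTNRYSWKMBDHV"
PROTEIN_ORDER = "ACDEFGHIKLMNPQRSTVWYX*"

_NEG = -1e30


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters for one sequence mode.

    Nucleotide defaults (+5/-4, gap 10/0.5) and protein defaults
    (BLOSUM62, gap 11/1) follow familiar megablast/blastp-like settings;
    all are overridable.
    """

    mode: str = "nucleotide"
    match: float = 5.0
    mismatch: float = -4.0
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.mode not in ("nucleotide", "protein"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        return cls(mode="nucleotide")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls(mode="protein", gap_open=11.0, gap_extend=1.0)

    @property
    def alphabet_order(self) -> str:
        return NUCLEOTIDE_ORDER if self.mode == "nucleotide" else PROTEIN_ORDER


@dataclass(frozen=True)
class Alignment:
    """A gapped global pairwise alignment with its column statistics."""

    row_a: str
    row_b: str
    score: float
    n_matches: int
    n_mismatches: int
    n_gap_columns: int

    @property
    def length(self) -> int:
        return len(self.row_a)

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        if self.n_matches + self.n_mismatches + self.n_gap_columns != len(self.row_a):
            raise ValueError("column counts do not sum to alignment length")


@lru_cache(maxsize=8)
def _score_matrix(scheme: ScoringScheme) -> np.ndarray:
    """Dense residue-index score matrix for a scheme.

    Nucleotide mode: match only for identical unambiguous bases; every
    ambiguity code (including N vs N) scores as a mismatch. Protein
    mode: the named substitution matrix, re-indexed to PROTEIN_ORDER.
    """
    if scheme.mode == "nucleotide":
        k = len(NUCLEOTIDE_ORDER)
        mat = np.full((k, k), scheme.mismatch, dtype=np.float64)
        for i in range(4):  # A, C, G, T
            mat[i, i] = scheme.match
        return mat
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load(scheme.substitution_matrix)
    k = len(PROTEIN_ORDER)
    mat = np.zeros((k, k), dtype=np.float64)
    for i, x in enumerate(PROTEIN_ORDER):
        for j, y in enumerate(PROTEIN_ORDER):
            mat[i, j] = blosum[x, y]
    return mat


@lru_cache(maxsize=4)
def _char_index(order: str) -> np.ndarray:
    table = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(order):
        table[ord(c)] = i
    return table


def _encode(seq: str, scheme: ScoringScheme) -> np.ndarray:
    table = _char_index(scheme.alphabet_order)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = table[arr]
    if (idx < 0).any():
        bad = chr(arr[np.argmax(idx < 0)])
        raise ValueError(f"residue {bad!r} not in the {scheme.mode} scoring alphabet")
    return idx.astype(np.int8)


@njit(cache=False)
def _nw_score_only(a, b, S, go, ge):  # pragma: no cover - jitted
    n, m = len(a), len(b)
    M = np.full(m + 1, _NEG)
    Ix = np.full(m + 1, _NEG)
    Iy = np.full(m + 1, _NEG)
    M[0] = 0.0
    for j in range(1, m + 1):
        Iy[j] = -(go + j * ge)
    for i in range(1, n + 1):
        dM, dIx, dIy = M[0], Ix[0], Iy[0]  # (i-1, 0) values
        M[0] = _NEG
        Ix[0] = -(go + i * ge)
        Iy[0] = _NEG
        for j in range(1, m + 1):
            pM, pIx, pIy = M[j], Ix[j], Iy[j]  # (i-1, j)
            # M from diagonal (i-1, j-1)
            best = dM
            if dIx > best:
                best = dIx
            if dIy > best:
                best = dIy
            newM = S[a[i - 1], b[j - 1]] + best
            # Ix from above (i-1, j)
            best = pM - go - ge
            if pIx - ge > best:
                best = pIx - ge
            if pIy - go - ge > best:
                best = pIy - go - ge
            newIx = best
            # Iy from left (i, j-1)
            best = M[j - 1] - go - ge
            if Ix[j - 1] - go - ge > best:
                best = Ix[j - 1] - go - ge
            if Iy[j - 1] - ge > best:
                best = Iy[j - 1] - ge
            newIy = best
            dM, dIx, dIy = pM, pIx, pIy
            M[j], Ix[j], Iy[j] = newM, newIx, newIy
    best = M[m]
    if Ix[m] > best:
        best = Ix[m]
    if Iy[m] > best:
        best = Iy[m]
    return best


@njit(cache=False)
def _nw_full(a, b, S, go, ge):  # pragma: no cover - jitted
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    # predecessor state per cell/state: 0 = M, 1 = Ix, 2 = Iy
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pIx = np.zeros((n + 1, m + 1), dtype=np.int8)
    pIy = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + i * ge)
        pIx[i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        Iy[0, j] = -(go + j * ge)
        pIy[0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal predecessor, preference M > Ix > Iy on ties
            best, arg = M[i - 1, j - 1], 0
            if Ix[i - 1, j - 1] > best:
                best, arg = Ix[i - 1, j - 1], 1
            if Iy[i - 1, j - 1] > best:
                best, arg = Iy[i - 1, j - 1], 2
            M[i, j] = S[a[i - 1], b[j - 1]] + best
            pM[i, j] = arg
            # Ix: from (i-1, j)
            best, arg = M[i - 1, j] - go - ge, 0
            if Ix[i - 1, j] - ge > best:
                best, arg = Ix[i - 1, j] - ge, 1
            if Iy[i - 1, j] - go - ge > best:
                best, arg = Iy[i - 1, j] - go - ge, 2
            Ix[i, j] = best
            pIx[i, j] = arg
            # Iy: from (i, j-1)
            best, arg = M[i, j - 1] - go - ge, 0
            if Ix[i, j - 1] - go - ge > best:
                best, arg = Ix[i, j - 1] - go - ge, 1
            if Iy[i, j - 1] - ge > best:
                best, arg = Iy[i, j - 1] - ge, 2
            Iy[i, j] = best
            pIy[i, j] = arg
    # final state: priority M > Ix > Iy encodes diagonal > up > left
    state = 0
    best = M[n, m]
    if Ix[n, m] > best:
        best, state = Ix[n, m], 1
    if Iy[n, m] > best:
        best, state = Iy[n, m], 2
    score = best
    # traceback into move arrays: 0 diag, 1 up, 2 left
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        moves[k] = state
        if state == 0:
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pIx[i, j]
            i -= 1
        else:
            state = pIy[i, j]
            j -= 1
        k += 1
    return score, moves[:k]


def alignment_score(
    seq_a: SequenceRecord | str, seq_b: SequenceRecord | str, scoring: ScoringScheme
) -> float:
    """Optimal global affine-gap alignment score (no traceback)."""
    a = _prep(seq_a, scoring)
    b = _prep(seq_b, scoring)
    return float(
        _nw_score_only(
            _encode(a, scoring),
            _encode(b, scoring),
            _score_matrix(scoring),
            float(scoring.gap_open),
            float(scoring.gap_extend),
        )
    )


def _prep(seq, scoring: ScoringScheme) -> str:
    if isinstance(seq, SequenceRecord):
        expected = "nucleotide" if scoring.mode == "nucleotide" else "protein"
        if seq.alphabet != expected:
            raise ValueError(
                f"record {seq.id!r} is {seq.alphabet}, scoring mode is {scoring.mode}"
            )
        seq = seq.residues
    seq = seq.upper()
    if not seq:
        raise ValueError("cannot align an empty sequence")
    return seq


def _is_match(x: str, y: str, mode: str) -> bool:
    if x != y:
        return False
    if mode == "nucleotide":
        return x in "ACGT"
    return x not in "X*"


def global_align(
    seq_a: SequenceRecord | str,
    seq_b: SequenceRecord | str,
    scoring: ScoringScheme | None = None,
) -> Alignment:
    """Globally align two sequences and return the alignment with statistics.

    The score is the maximum over all global alignments under affine-gap
    scoring with end gaps penalized; the traceback is deterministic
    (diagonal > up > left on ties).
    """
    if scoring is None:
        scoring = ScoringScheme.nucleotide_default()
    a = _prep(seq_a, scoring)
    b = _prep(seq_b, scoring)
    score, moves = _nw_full(
        _encode(a, scoring),
        _encode(b, scoring),
        _score_matrix(scoring),
        float(scoring.gap_open),
        float(scoring.gap_extend),
    )
    row_a, row_b = [], []
    i = j = 0
    for mv in moves[::-1]:
        if mv == 0:
            row_a.append(a[i])
            row_b.append(b[j])
            i += 1
            j += 1
        elif mv == 1:
            row_a.append(a[i])
            row_b.append("-")
            i += 1
        else:
            row_a.append("-")
            row_b.append(b[j])
            j += 1
    ra, rb = "".join(row_a), "".join(row_b)
    n_match = n_mis = n_gap = 0
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            n_gap += 1
        elif _is_match(x, y, scoring.mode):
            n_match += 1
        else:
            n_mis += 1
    return Alignment(ra, rb, float(score), n_match, n_mis, n_gap)


def percent_identity(aln: Alignment, include_terminal_gaps: bool = True) -> float:
    """Percent identity of an alignment: 100 * matches / columns.

    With ``include_terminal_gaps`` (default) every column counts in the
    denominator. Otherwise leading and trailing gap runs are dropped
    before counting — matches are unaffected because terminal gap
    columns are never matches.
    """
    if include_terminal_gaps:
        return 100.0 * aln.n_matches / aln.length
    lo, hi = 0, aln.length
    while lo < hi and (aln.row_a[lo] == "-" or aln.row_b[lo] == "-"):
        lo += 1
    while hi > lo and (aln.row_a[hi - 1] == "-" or aln.row_b[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    return 100.0 * aln.n_matches / (hi - lo)
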