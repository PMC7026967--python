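"""Pairwise sequence alignment and genetic distance.

The OTU pipeline defines genetic distance between two reads as the
fraction of differing columns (mismatches plus gapped columns) in a
global affine-gap alignment, with terminal gap columns excluded from
both numerator and denominator.  Default scoring: match +1, mismatch
-1, gap open -2 (first gap column), gap extend -1 (each further
column).  Gap columns in opposite sequences are never adjacent (the
X<->Y transition is disallowed, as in most affine-gap DP codes).

Because several co-optimal alignments can disagree on the number of
mismatch vs gap columns, the traceback is canonical: at equal scores
the diagonal move is preferred, then the vertical (gap in the second
sequence), then the horizontal.  Any independent implementation of the
same rules reproduces the distance bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Scoring",
    "AlignmentResult",
    "LocalHit",
    "encode_dna",
    "align_global",
    "align_local",
    "pairwise_distance",
    "hamming",
]

_ENCODE = np.full(256, 4, dtype=np.uint8)  # everything unknown -> N
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_NEG = -1e30


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring parameters (gap_open = cost of the first gap
    column of a run, gap_extend = cost of each subsequent column)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with its column-based genetic distance."""

    aligned_a: str
    aligned_b: str
    score: float
    distance: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")


@dataclass(frozen=True)
class LocalHit:
    """Local (Smith-Waterman) alignment summary.

    Spans are 1-based inclusive positions on the original (unclipped)
    sequences; identity = matches / aligned columns of the local block.
    """

    score: float
    matches: int
    columns: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string over {A,C,G,T,N} as uint8 codes 0..4."""
    if not seq:
        raise ValueError("empty sequence")
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend, local):
    """Three-state affine DP.

    Returns (score, ops, i0, j0, i1, j1): ops is the canonical traceback
    (0=diag, 1=up/consume a, 2=left/consume b) of the scored path, which
    runs from cell (i0, j0) to (i1, j1).  In global mode i0=j0=0 and
    (i1, j1)=(n, m); in local mode the path starts and ends on the
    maximal-scoring block (Smith-Waterman with affine gaps).

    Tie rules (canonical traceback): in M the diagonal predecessor is
    preferred in the order local-start, M, X, Y (global: M, X, Y); in
    X/Y opening from M is preferred over extending.  The local end cell
    is the first maximal M cell in row-major order.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (vertical, consumes a)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (horizontal, consumes b)
    # traceback pointers: predecessor state 0=M,1=X,2=Y,3=local start
    # (and for X/Y: 0=open from M, 1=extend)
    tb_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_y = np.zeros((n + 1, m + 1), dtype=np.int8)

    if not local:
        M[0, 0] = 0.0
        for i in range(1, n + 1):
            X[i, 0] = gap_open + gap_extend * (i - 1)
            tb_x[i, 0] = 1 if i > 1 else 0
        for j in range(1, m + 1):
            Y[0, j] = gap_open + gap_extend * (j - 1)
            tb_y[0, j] = 1 if j > 1 else 0

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            if local:
                best = 0.0
                ptr = 3
            else:
                best = M[i - 1, j - 1]
                ptr = 0
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]
                ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            tb_m[i, j] = ptr
            # X: vertical; open from M preferred over extend at ties
            op = M[i - 1, j] + gap_open
            ex = X[i - 1, j] + gap_extend
            if op >= ex:
                X[i, j] = op
                tb_x[i, j] = 0
            else:
                X[i, j] = ex
                tb_x[i, j] = 1
            # Y: horizontal
            op = M[i, j - 1] + gap_open
            ex = Y[i, j - 1] + gap_extend
            if op >= ex:
                Y[i, j] = op
                tb_y[i, j] = 0
            else:
                Y[i, j] = ex
                tb_y[i, j] = 1

    if local:
        best = _NEG
        bi, bj = 1, 1
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if M[i, j] > best:
                    best = M[i, j]
                    bi, bj = i, j
        state = 0
    else:
        best = M[n, m]
        state = 0
        if X[n, m] > best:
            best = X[n, m]
            state = 1
        if Y[n, m] > best:
            best = Y[n, m]
            state = 2
        bi, bj = n, m

    # traceback from (bi, bj); stops at (0,0) or at a local start
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = bi, bj
    while True:
        if state == 0:
            if i == 0 and j == 0:
                break
            k -= 1
            ops[k] = 0
            ptr = tb_m[i, j]
            i -= 1
            j -= 1
            if ptr == 3:
                break
            state = ptr
        elif state == 1:
            k -= 1
            ops[k] = 1
            state = 1 if tb_x[i, j] == 1 else 0
            i -= 1
            if i == 0 and j == 0:
                break
        else:
            k -= 1
            ops[k] = 2
            state = 2 if tb_y[i, j] == 1 else 0
            j -= 1
            if i == 0 and j == 0:
                break
    return best, ops[k:], i, j, bi, bj


@njit(cache=True)
def _distance_from_ops(a, b, ops):
    """Mismatch+gap column fraction, terminal gap runs excluded."""
    L = len(ops)
    lo = 0
    while lo < L and ops[lo] != 0:
        lo += 1
    hi = L
    while hi > lo and ops[hi - 1] != 0:
        hi -= 1
    i = 0
    j = 0
    for k in range(lo):
        if ops[k] == 1:
            i += 1
        elif ops[k] == 2:
            j += 1
    diff = 0
    cols = 0
    for k in range(lo, hi):
        cols += 1
        if ops[k] == 0:
            if a[i] != b[j] or a[i] >= 4:
                diff += 1
            i += 1
            j += 1
        elif ops[k] == 1:
            diff += 1
            i += 1
        else:
            diff += 1
            j += 1
    if cols == 0:
        return 1.0
    return diff / cols


def _gapped_strings(sa: str, sb: str, ops: np.ndarray) -> tuple[str, str]:
    out_a, out_b = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            out_a.append(sa[i])
            out_b.append(sb[j])
            i += 1
            j += 1
        elif op == 1:
            out_a.append(sa[i])
            out_b.append("-")
            i += 1
        else:
            out_a.append("-")
            out_b.append(sb[j])
            j += 1
    return "".join(out_a), "".join(out_b)


def align_global(seq_a: str, seq_b: str, scoring: Scoring = Scoring()) -> AlignmentResult:
    """Global affine-gap alignment with canonical traceback."""
    a = encode_dna(seq_a)
    b = encode_dna(seq_b)
    score, ops, *_ = _gotoh(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, False
    )
    dist = float(_distance_from_ops(a, b, ops))
    ga, gb = _gapped_strings(seq_a, seq_b, ops)
    return AlignmentResult(ga, gb, float(score), dist)


def pairwise_distance(seq_a: str, seq_b: str, scoring: Scoring = Scoring()) -> float:
    """Genetic distance in [0, 1]: differing columns / aligned columns,
    terminal gaps excluded.  0 for identical sequences.

    The optimal score is symmetric but the canonical traceback is not
    (its tie rules distinguish the two gap states), so the arguments
    are ordered lexicographically first, making the distance exactly
    symmetric."""
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    a = encode_dna(seq_a)
    b = encode_dna(seq_b)
    _, ops, *_ = _gotoh(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, False
    )
    return float(_distance_from_ops(a, b, ops))


def align_local(query: str, subject: str, scoring: Scoring = Scoring()) -> LocalHit:
    """Local affine-gap alignment of query against subject.

    Low-identity query ends are clipped instead of forced into the
    alignment — the behaviour the end-integrity screen relies on (a
    clean query is spanned end to end; junk ends score negatively and
    are dropped from the maximal-scoring block).
    """
    q = encode_dna(query)
    s = encode_dna(subject)
    score, ops, i0, j0, _, _ = _gotoh(
        q, s, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, True
    )
    # strip any (paid) terminal gap runs inside the scored path
    L = len(ops)
    lo = 0
    while lo < L and ops[lo] != 0:
        lo += 1
    hi = L
    while hi > lo and ops[hi - 1] != 0:
        hi -= 1
    qi = i0 + sum(1 for k in range(lo) if ops[k] == 1)
    sj = j0 + sum(1 for k in range(lo) if ops[k] == 2)
    matches = 0
    cols = 0
    i, j = qi, sj
    for k in range(lo, hi):
        cols += 1
        if ops[k] == 0:
            if q[i] == s[j] and q[i] < 4:
                matches += 1
            i += 1
            j += 1
        elif ops[k] == 1:
            i += 1
        else:
            j += 1
    return LocalHit(
        score=float(score),
        matches=matches,
        columns=cols,
        q_start=qi + 1,
        q_end=i,
        s_start=sj + 1,
        s_end=j,
    )


def hamming(seq_a: str, seq_b: str) -> int:
    """Number of differing positions between equal-length strings."""
    if len(seq_a) != len(seq_b):
        raise ValueError("hamming requires equal lengths")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    return int((a != b).sum())
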