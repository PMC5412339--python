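"""Affine-gap global alignment kernel (Gotoh three-state DP).

Kept separate from the public indel-calling API because it works on numeric
code arrays and is numba-compiled. States: M (diagonal, consume one base of
each), X ("up", consume a reference base against a gap in the query — a
deletion), Y ("left", consume a query base against a gap in the reference —
an insertion). Ties are broken M > X > Y at every choice point, which makes
the traceback fully deterministic.

A gap of length L costs ``gap_open + L * gap_extend`` (both <= 0).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

# traceback op codes emitted by the kernel
OP_DIAG = 0  # ref base vs query base
OP_UP = 1    # ref base vs gap (deletion in query)
OP_LEFT = 2  # gap vs query base (insertion)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
_N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Map an ACGTN string to uint8 codes (N = 4, never matches)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError(f"non-ACGTN character in sequence {seq!r}")
    return arr


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + i * gap_extend
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + j * gap_extend
        pY[0, j] = 2

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai != _N_CODE) else mismatch

            # M: best predecessor at (i-1, j-1); prefer M > X > Y on ties
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr

            # X: gap in query, consume a[i-1]
            best = M[i - 1, j] + gap_open + gap_extend
            ptr = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = 1
            if Y[i - 1, j] + gap_open + gap_extend > best:
                best = Y[i - 1, j] + gap_open + gap_extend
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr

            # Y: gap in ref, consume b[j-1]
            best = M[i, j - 1] + gap_open + gap_extend
            ptr = 0
            if X[i, j - 1] + gap_open + gap_extend > best:
                best = X[i, j - 1] + gap_open + gap_extend
                ptr = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr

    # final state: prefer M > X > Y on ties
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = OP_DIAG
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = OP_UP
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = OP_LEFT
            state = pY[i, j]
            j -= 1
    return score, ops[k:]


def gotoh_align(
    ref: str, query: str,
    match: float, mismatch: float, gap_open: float, gap_extend: float,
) -> tuple[float, np.ndarray]:
    """Optimal global alignment score and traceback ops for two sequences."""
    return _gotoh(
        encode(ref), encode(query),
        float(match), float(mismatch), float(gap_open), float(gap_extend),
    )
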