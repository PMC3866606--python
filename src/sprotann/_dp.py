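"""Affine-gap dynamic-programming alignment kernel.

One semi-global Needleman-Wunsch routine over an arbitrary pairwise score
matrix, shared by the distance-based structure aligner (TM-align-style score
1/(1+(d/d0)^2), gap open 0.6, no extension penalty) and the profile-to-
sequence mapper. JIT-compiled with numba when available; a pure-Python
fallback keeps the package importable without it.
"""

from __future__ import annotations

import numpy as np

_M, _X, _Y = 0, 1, 2
_NEG = -1e30


def _affine_dp_py(S, gap_open, gap_ext, free_ends):
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in columns: row i unmatched
    Y = np.full((n + 1, m + 1), _NEG)  # gap in rows: column j unmatched
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_ends else -(gap_open + (i - 1) * gap_ext)
        ptr[_X, i, 0] = _X
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_ends else -(gap_open + (j - 1) * gap_ext)
        ptr[_Y, 0, j] = _Y
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[i - 1, j - 1]
            best = M[i - 1, j - 1]
            state = _M
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                state = _X
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                state = _Y
            M[i, j] = best + s
            ptr[_M, i, j] = state

            a = M[i - 1, j] - gap_open
            b = X[i - 1, j] - gap_ext
            if a >= b:
                X[i, j] = a
                ptr[_X, i, j] = _M
            else:
                X[i, j] = b
                ptr[_X, i, j] = _X

            a = M[i, j - 1] - gap_open
            b = Y[i, j - 1] - gap_ext
            if a >= b:
                Y[i, j] = a
                ptr[_Y, i, j] = _M
            else:
                Y[i, j] = b
                ptr[_Y, i, j] = _Y

    # terminal cell: with free ends the best alignment may stop anywhere on
    # the last row/column (trailing gaps cost nothing)
    best_score = max(M[n, m], X[n, m], Y[n, m])
    bstate = _M if M[n, m] >= max(X[n, m], Y[n, m]) else (
        _X if X[n, m] >= Y[n, m] else _Y)
    bi, bj = n, m
    if free_ends:
        for i in range(1, n + 1):
            if M[i, m] > best_score:
                best_score = M[i, m]
                bi, bj, bstate = i, m, _M
        for j in range(1, m + 1):
            if M[n, j] > best_score:
                best_score = M[n, j]
                bi, bj, bstate = n, j, _M

    # traceback
    ai = np.empty(min(n, m), dtype=np.int64)
    bj_arr = np.empty(min(n, m), dtype=np.int64)
    k = 0
    i, j, state = bi, bj, bstate
    while i > 0 or j > 0:
        if state == _M:
            if i == 0 or j == 0:
                break
            prev = ptr[_M, i, j]
            ai[k] = i - 1
            bj_arr[k] = j - 1
            k += 1
            i -= 1
            j -= 1
            state = prev
        elif state == _X:
            prev = ptr[_X, i, j]
            i -= 1
            state = prev
        else:
            prev = ptr[_Y, i, j]
            j -= 1
            state = prev
    return ai[:k][::-1].copy(), bj_arr[:k][::-1].copy(), best_score


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _affine_dp_jit = njit(cache=True)(_affine_dp_py)

    def affine_dp(S: np.ndarray, gap_open: float, gap_ext: float = 0.0,
                  free_ends: bool = True):
        """Align rows to columns of score matrix S; returns (rows, cols, score).

        Gap model: affine with the stated open/extension penalties; when
        ``free_ends`` is True, leading and trailing gaps are free
        (semi-global alignment).
        """
        return _affine_dp_jit(np.ascontiguousarray(S, dtype=np.float64),
                              float(gap_open), float(gap_ext), bool(free_ends))
except ImportError:  # pragma: no cover
    def affine_dp(S, gap_open, gap_ext=0.0, free_ends=True):
        return _affine_dp_py(np.ascontiguousarray(S, dtype=np.float64),
                             float(gap_open), float(gap_ext), bool(free_ends))
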