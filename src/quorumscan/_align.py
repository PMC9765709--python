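"""Dynamic-programming alignment kernels.

Three primitives, all exact DP with traceback:

* :func:`profile_local_align` — Smith–Waterman–Gotoh of a position-specific
  score matrix against a residue sequence (affine gaps), returning the best
  local score and the number of profile columns consumed (for coverage).
* :func:`fit_align` — semi-global alignment of a short query inside a longer
  target (query global, target local), returning match and aligned counts.
* :func:`global_align` — Needleman–Wunsch with linear gaps, returning match
  count and alignment length.

Kernels are JIT-compiled with numba; inputs are int8 residue indices.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=False)
def _profile_local_core(prof, seq, gap_open, gap_extend):
    L = prof.shape[0]
    N = seq.shape[0]
    M = np.full((L + 1, N + 1), 0.0)
    Ix = np.full((L + 1, N + 1), NEG)
    Iy = np.full((L + 1, N + 1), NEG)
    # pointers: M: 0 local-start, 1 from M, 2 from Ix, 3 from Iy
    pM = np.zeros((L + 1, N + 1), dtype=np.int8)
    pX = np.zeros((L + 1, N + 1), dtype=np.int8)
    pY = np.zeros((L + 1, N + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, N + 1):
            s = prof[i - 1, seq[j - 1]]
            # match state
            d = 0.0
            p = 0
            if M[i - 1, j - 1] > d:
                d = M[i - 1, j - 1]
                p = 1
            if Ix[i - 1, j - 1] > d:
                d = Ix[i - 1, j - 1]
                p = 2
            if Iy[i - 1, j - 1] > d:
                d = Iy[i - 1, j - 1]
                p = 3
            m = d + s
            if m < 0.0:
                m = 0.0
                p = 0
            M[i, j] = m
            pM[i, j] = p
            # profile column skipped in sequence (deletion)
            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            if a >= b:
                Ix[i, j] = a
                pX[i, j] = 1
            else:
                Ix[i, j] = b
                pX[i, j] = 2
            # sequence residue inserted relative to profile
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            if a >= b:
                Iy[i, j] = a
                pY[i, j] = 1
            else:
                Iy[i, j] = b
                pY[i, j] = 3
            if m > best:
                best = m
                bi = i
                bj = j
    # traceback from best M cell
    match_cols = 0
    prof_hi = bi
    prof_lo = bi
    seq_hi = bj
    seq_lo = bj
    i = bi
    j = bj
    state = 1  # in M
    while i > 0 and j > 0:
        if state == 1:
            match_cols += 1
            prof_lo = i - 1
            seq_lo = j - 1
            p = pM[i, j]
            i -= 1
            j -= 1
            if p == 0:
                break
            state = p
        elif state == 2:
            state = pX[i, j]
            i -= 1
        else:
            state = pY[i, j]
            j -= 1
    return best, match_cols, prof_lo, prof_hi, seq_lo, seq_hi


@njit(cache=False)
def _fit_core(q, t, match, mismatch, gap):
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1))
    P = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 diag, 2 up(gap in t), 3 left
    for i in range(1, m + 1):
        H[i, 0] = H[i - 1, 0] + gap
        P[i, 0] = 2
    # first row stays 0: leading target residues are free
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            d = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            l = H[i, j - 1] + gap
            if d >= u and d >= l:
                H[i, j] = d
                P[i, j] = 1
            elif u >= l:
                H[i, j] = u
                P[i, j] = 2
            else:
                H[i, j] = l
                P[i, j] = 3
    # free trailing target residues: best cell in last row
    bj = 0
    best = NEG
    for j in range(n + 1):
        if H[m, j] > best:
            best = H[m, j]
            bj = j
    matches = 0
    q_aligned = 0
    i = m
    j = bj
    while i > 0:
        p = P[i, j]
        if p == 1:
            if q[i - 1] == t[j - 1]:
                matches += 1
            q_aligned += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, matches, q_aligned


@njit(cache=False)
def _global_core(a, b, match, mismatch, gap):
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1))
    P = np.zeros((m + 1, n + 1), dtype=np.int8)
    for i in range(1, m + 1):
        H[i, 0] = H[i - 1, 0] + gap
        P[i, 0] = 2
    for j in range(1, n + 1):
        H[0, j] = H[0, j - 1] + gap
        P[0, j] = 3
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            d = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            l = H[i, j - 1] + gap
            if d >= u and d >= l:
                H[i, j] = d
                P[i, j] = 1
            elif u >= l:
                H[i, j] = u
                P[i, j] = 2
            else:
                H[i, j] = l
                P[i, j] = 3
    matches = 0
    cols = 0
    i = m
    j = n
    while i > 0 or j > 0:
        p = P[i, j]
        cols += 1
        if p == 1:
            if a[i - 1] == b[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return H[m, n], matches, cols


def profile_local_align(
    prof: np.ndarray, seq: np.ndarray, gap_open: float = 11.0, gap_extend: float = 1.0
) -> tuple[float, int, tuple[int, int], tuple[int, int]]:
    """Best local alignment of a score profile (L x 20) against ``seq``.

    Returns ``(score, matched_columns, (prof_lo, prof_hi), (seq_lo, seq_hi))``
    with half-open spans; matched_columns counts aligned (match-state)
    profile columns, mismatches included.
    """
    prof = np.ascontiguousarray(prof, dtype=np.float64)
    seq = np.ascontiguousarray(seq, dtype=np.int8)
    score, cols, plo, phi, slo, shi = _profile_local_core(
        prof, seq, float(gap_open), float(gap_extend)
    )
    return float(score), int(cols), (int(plo), int(phi)), (int(slo), int(shi))


def fit_align(
    query: np.ndarray,
    target: np.ndarray,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> tuple[float, int, int]:
    """Align ``query`` globally inside ``target`` (target ends free).

    Returns ``(score, matches, query_residues_aligned)``.
    """
    score, matches, q_aligned = _fit_core(
        np.ascontiguousarray(query, dtype=np.int8),
        np.ascontiguousarray(target, dtype=np.int8),
        float(match),
        float(mismatch),
        float(gap),
    )
    return float(score), int(matches), int(q_aligned)


def global_align(
    a: np.ndarray,
    b: np.ndarray,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -3.0,
) -> tuple[float, int, int]:
    """Needleman–Wunsch; returns ``(score, matches, alignment_columns)``."""
    score, matches, cols = _global_core(
        np.ascontiguousarray(a, dtype=np.int8),
        np.ascontiguousarray(b, dtype=np.int8),
        float(match),
        float(mismatch),
        float(gap),
    )
    return float(score), int(matches), int(cols)
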