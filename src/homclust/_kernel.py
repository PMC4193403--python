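"""Numba Smith-Waterman kernels.

Two kernels share one recurrence so their scores agree bitwise:

  E[i,j] = max(H[i,j-1] - open, E[i,j-1] - extend)   gap consuming b_j
  F[i,j] = max(H[i-1,j] - open, F[i-1,j] - extend)   gap consuming a_i
  H[i,j] = max(0, H[i-1,j-1] + S[a_i, b_j], F[i,j], E[i,j])

so a gap of length k costs open + (k-1)*extend. Tie-breaking is fixed:
the best cell is the first maximum in row-major order (smallest end on a,
then on b); cell choice prefers diagonal over F (up) over E (left); gap
states prefer closing (coming from H) over extending.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def sw_score_kernel(a, b, S, gap_open, gap_extend):
    """Best local alignment score only; O(n) memory."""
    m = a.shape[0]
    n = b.shape[0]
    Hprev = np.zeros(n + 1)
    Hcur = np.zeros(n + 1)
    F = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, m + 1):
        ai = a[i - 1]
        e = NEG
        Hcur[0] = 0.0
        for j in range(1, n + 1):
            eo = Hcur[j - 1] - gap_open
            ee = e - gap_extend
            e = eo if eo >= ee else ee
            fo = Hprev[j] - gap_open
            fe = F[j] - gap_extend
            fj = fo if fo >= fe else fe
            F[j] = fj
            h = Hprev[j - 1] + S[ai, b[j - 1]]
            if fj > h:
                h = fj
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            Hcur[j] = h
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
    return best


@njit(cache=True)
def sw_traceback_kernel(a, b, S, gap_open, gap_extend):
    """Best local alignment with intervals.

    Returns (score, qstart, qend, sstart, send) with 0-based half-open
    intervals of the residues each sequence contributes to the alignment.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    PH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up(F), 3 left(E)
    PF = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 opened from H
    PE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            eo = H[i, j - 1] - gap_open
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                PE[i, j] = 1
            else:
                E[i, j] = ee
                PE[i, j] = 0
            fo = H[i - 1, j] - gap_open
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                PF[i, j] = 1
            else:
                F[i, j] = fe
                PF[i, j] = 0
            h = H[i - 1, j - 1] + S[ai, b[j - 1]]
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0.0:
        return 0.0, 0, 0, 0, 0
    # traceback; state 0 = H, 2 = F, 3 = E
    i = bi
    j = bj
    state = 0
    while True:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            p = PF[i, j]
            i -= 1
            state = 0 if p == 1 else 2
        else:
            p = PE[i, j]
            j -= 1
            state = 0 if p == 1 else 3
    return best, i, bi, j, bj
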