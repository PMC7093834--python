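"""Numba kernels for affine-gap local alignment (Gotoh recurrences).

Scoring is driven by a substitution matrix indexed by the int8 sequence
codes (identity +1/-1 for DNA, BLOSUM62 for protein); a gap of length L
costs ``gap_open + L * gap_extend`` (both negative).  Codes whose matrix
row is uniformly negative act as hard mismatches (used to mask found hits).

Tie-breaking is fixed so that independent implementations can agree
exactly: the best cell is the first maximum scanning target positions then
query positions; traceback prefers diagonal, then a gap in the query
(target consumed), then a gap in the target.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 7)


@njit(cache=True)
def best_local_cell(q, t, submat, gap_open, gap_extend, xdrop):
    """Score-only local DP; returns (best_score, end_i, end_j).

    end_i/end_j are 1-based DP indices (alignment ends before q[end_i],
    t[end_j]).  If ``xdrop`` > 0, scanning stops once a target column's
    best running score falls more than xdrop below the global best (speed
    heuristic; a large xdrop makes the scan exhaustive).
    """
    n = q.shape[0]
    m = t.shape[0]
    h_prev = np.zeros(n + 1, np.int64)
    e_prev = np.full(n + 1, NEG, np.int64)
    h_cur = np.zeros(n + 1, np.int64)
    e_cur = np.full(n + 1, NEG, np.int64)
    best = 0
    best_i = 0
    best_j = 0
    for j in range(1, m + 1):
        h_cur[0] = 0
        e_cur[0] = NEG
        f = NEG
        col_best = 0
        tj = t[j - 1]
        for i in range(1, n + 1):
            e = e_prev[i] + gap_extend
            eo = h_prev[i] + gap_open + gap_extend
            if eo > e:
                e = eo
            f = f + gap_extend
            fo = h_cur[i - 1] + gap_open + gap_extend
            if fo > f:
                f = fo
            h = h_prev[i - 1] + submat[q[i - 1], tj]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[i] = h
            e_cur[i] = e
            if h > best:
                best = h
                best_i = i
                best_j = j
            if h > col_best:
                col_best = h
        h_prev, h_cur = h_cur, h_prev
        e_prev, e_cur = e_cur, e_prev
        if xdrop > 0 and best > 0 and col_best < best - xdrop:
            break
    return best, best_i, best_j


@njit(cache=True)
def local_traceback(q, t, submat, gap_open, gap_extend):
    """Full-matrix local DP with traceback on (small) inputs.

    Returns (score, q_start, q_end, t_start, t_end, matches, columns) for
    the best local alignment under the module tie-break rules; ``matches``
    counts identical residues (not positive-score pairs).
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), NEG, np.int64)
    F = np.full((n + 1, m + 1), NEG, np.int64)
    best = 0
    best_i = 0
    best_j = 0
    for j in range(1, m + 1):
        tj = t[j - 1]
        for i in range(1, n + 1):
            e = E[i, j - 1] + gap_extend
            eo = H[i, j - 1] + gap_open + gap_extend
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            fo = H[i - 1, j] + gap_open + gap_extend
            if fo > f:
                f = fo
            F[i, j] = f
            h = H[i - 1, j - 1] + submat[q[i - 1], tj]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                best_i = i
                best_j = j
    # traceback
    i = best_i
    j = best_j
    matches = 0
    cols = 0
    state = 0  # 0 = H, 1 = E (gap in query), 2 = F (gap in target)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + submat[q[i - 1], t[j - 1]]:
                cols += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            if E[i, j] == H[i, j - 1] + gap_open + gap_extend:
                state = 0
            j -= 1
        else:
            cols += 1
            if F[i, j] == H[i - 1, j] + gap_open + gap_extend:
                state = 0
            i -= 1
    return best, i, best_i, j, best_j, matches, cols
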