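"""Affine-gap global alignment kernels (Gotoh three-state recursion).

State convention: ``Hm`` ends in a residue-residue column, ``Ix`` ends in a
column consuming a residue of sequence A against a gap ("up" move), ``Iy``
the mirror ("left" move).  The first position of a gap costs
``gap_open + gap_extend``; each further position ``gap_extend``.  With free
end gaps the DP is semi-global: leading gap states cost 0 and the optimum is
taken over the last row and column.

Traceback is deterministic: diagonal is preferred over up over left, and
with free end gaps the end cell closest to the (n, m) corner wins ties.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def gotoh_fill(M, gap_open_total, gap_ext, free_ends):
    """Fill the three Gotoh matrices for a column-score matrix ``M``."""
    n, m = M.shape
    Hm = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    Hm[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = 0.0 if free_ends else -(gap_open_total + (i - 1) * gap_ext)
    for j in range(1, m + 1):
        Iy[0, j] = 0.0 if free_ends else -(gap_open_total + (j - 1) * gap_ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = Hm[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            Hm[i, j] = M[i - 1, j - 1] + best

            x = Hm[i - 1, j] - gap_open_total
            if Ix[i - 1, j] - gap_ext > x:
                x = Ix[i - 1, j] - gap_ext
            if Iy[i - 1, j] - gap_open_total > x:
                x = Iy[i - 1, j] - gap_open_total
            Ix[i, j] = x

            y = Hm[i, j - 1] - gap_open_total
            if Iy[i, j - 1] - gap_ext > y:
                y = Iy[i, j - 1] - gap_ext
            if Ix[i, j - 1] - gap_open_total > y:
                y = Ix[i, j - 1] - gap_open_total
            Iy[i, j] = y
    return Hm, Ix, Iy


@njit(cache=True)
def gotoh_score(ai, bi, S, gap_open_total, gap_ext, free_ends):
    """Score-only Gotoh over integer-encoded sequences; O(m) memory."""
    n = ai.shape[0]
    m = bi.shape[0]
    Hp = np.full(m + 1, NEG)
    Xp = np.full(m + 1, NEG)
    Yp = np.full(m + 1, NEG)
    Hc = np.empty(m + 1)
    Xc = np.empty(m + 1)
    Yc = np.empty(m + 1)
    Hp[0] = 0.0
    for j in range(1, m + 1):
        Yp[j] = 0.0 if free_ends else -(gap_open_total + (j - 1) * gap_ext)

    best_end = NEG
    if free_ends:
        # end cell (0, m): whole of A as trailing gap.
        for v in (Hp[m], Xp[m], Yp[m]):
            if v > best_end:
                best_end = v

    for i in range(1, n + 1):
        Hc[0] = NEG
        Yc[0] = NEG
        Xc[0] = 0.0 if free_ends else -(gap_open_total + (i - 1) * gap_ext)
        a = ai[i - 1]
        for j in range(1, m + 1):
            best = Hp[j - 1]
            if Xp[j - 1] > best:
                best = Xp[j - 1]
            if Yp[j - 1] > best:
                best = Yp[j - 1]
            Hc[j] = S[a, bi[j - 1]] + best

            x = Hp[j] - gap_open_total
            if Xp[j] - gap_ext > x:
                x = Xp[j] - gap_ext
            if Yp[j] - gap_open_total > x:
                x = Yp[j] - gap_open_total
            Xc[j] = x

            y = Hc[j - 1] - gap_open_total
            if Yc[j - 1] - gap_ext > y:
                y = Yc[j - 1] - gap_ext
            if Xc[j - 1] - gap_open_total > y:
                y = Xc[j - 1] - gap_open_total
            Yc[j] = y
        if free_ends:
            for v in (Hc[m], Xc[m], Yc[m]):
                if v > best_end:
                    best_end = v
        Hp, Hc = Hc, Hp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp

    if free_ends:
        for j in range(m + 1):
            for v in (Hp[j], Xp[j], Yp[j]):
                if v > best_end:
                    best_end = v
        return best_end
    best = Hp[m]
    if Xp[m] > best:
        best = Xp[m]
    if Yp[m] > best:
        best = Yp[m]
    return best


def _argmax3(h, x, y):
    """State preference on ties: diagonal (Hm) > up (Ix) > left (Iy)."""
    if h >= x and h >= y:
        return 0, h
    if x >= y:
        return 1, x
    return 2, y


def traceback(M, Hm, Ix, Iy, gap_open_total, gap_ext, free_ends):
    """Recover one optimal alignment as a list of column index pairs.

    Each column is ``(i, j)`` with 0-based residue indices, -1 marking a
    gap.  Returns ``(columns, score)``.
    """
    n, m = M.shape
    if free_ends:
        # Choose the end cell: scan last column then last row, keeping
        # strictly better cells, starting from the (n, m) corner.
        ei, ej = n, m
        state, best = _argmax3(Hm[n, m], Ix[n, m], Iy[n, m])
        for i in range(n + 1):
            s, v = _argmax3(Hm[i, m], Ix[i, m], Iy[i, m])
            if v > best:
                ei, ej, state, best = i, m, s, v
        for j in range(m + 1):
            s, v = _argmax3(Hm[n, j], Ix[n, j], Iy[n, j])
            if v > best:
                ei, ej, state, best = n, j, s, v
    else:
        ei, ej = n, m
        state, best = _argmax3(Hm[n, m], Ix[n, m], Iy[n, m])
    score = best

    cols = []
    # Trailing free end gaps.
    for j in range(m, ej, -1):
        cols.append((-1, j - 1))
    for i in range(n, ei, -1):
        cols.append((i - 1, -1))

    i, j = ei, ej
    while i > 0 or j > 0:
        if i == 0:
            cols.append((-1, j - 1))
            j -= 1
            continue
        if j == 0:
            cols.append((i - 1, -1))
            i -= 1
            continue
        if state == 0:
            cols.append((i - 1, j - 1))
            state, _ = _argmax3(Hm[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            cols.append((i - 1, -1))
            v = Ix[i, j]
            # Predecessor preference mirrors the move preference: Hm > Ix > Iy.
            if Hm[i - 1, j] - gap_open_total == v:
                state = 0
            elif Ix[i - 1, j] - gap_ext == v:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            cols.append((-1, j - 1))
            v = Iy[i, j]
            if Hm[i, j - 1] - gap_open_total == v:
                state = 0
            elif Ix[i, j - 1] - gap_open_total == v:
                state = 1
            else:
                state = 2
            j -= 1
        # The equality tests rely on exact float comparison, which holds
        # because every score is a sum of integer-valued terms.
    cols.reverse()
    return cols, score
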