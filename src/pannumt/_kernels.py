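"""Numba kernels for affine-gap local alignment (seed extension + traceback).

Scores are integers; a gap of length L costs ``gap_open + gap_extend * L``.
The X-drop extension abandons dynamic-programming cells whose score falls
more than ``xdrop`` below the best score seen anywhere in the extension,
which bounds the active band to a few tens of columns for the schemes in
use and makes extension cost roughly linear in alignment length.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(1 << 29)


@njit(cache=True)
def xdrop_extend(q, s, reward, penalty, gap_open, gap_extend, xdrop):
    """Best-scoring extension of an alignment anchored at (0, 0).

    Aligns prefixes of ``q`` against prefixes of ``s`` (both uint8 code
    arrays); the caller orients the arrays so extension proceeds rightward,
    and passes reversed views for leftward extension.  Returns
    ``(best_score, qi, sj)`` meaning ``q[:qi]`` aligns to ``s[:sj]``.
    Codes >= 4 (ambiguous bases) never match.  Ties resolve to the cell
    reached first in row-major order, so results are deterministic.
    """
    m, n = len(q), len(s)
    go_ge = gap_open + gap_extend
    H = np.full(n + 1, NEG, dtype=np.int64)
    F = np.full(n + 1, NEG, dtype=np.int64)
    Hn = np.full(n + 1, NEG, dtype=np.int64)
    Fn = np.full(n + 1, NEG, dtype=np.int64)

    best = 0
    bi = 0
    bj = 0

    # row 0: leading gaps consuming the subject
    H[0] = 0
    lo = 0
    hi = 0
    j = 1
    while j <= n:
        v = -(go_ge + gap_extend * (j - 1))
        if v < -xdrop:
            break
        H[j] = v
        hi = j
        j += 1

    for i in range(1, m + 1):
        qc = q[i - 1]
        cutoff = best - xdrop
        new_lo = -1
        new_hi = -1
        e = NEG
        j = lo
        while j <= n:
            sub = NEG
            if lo <= j - 1 <= hi and H[j - 1] > NEG:
                if qc == s[j - 1] and qc < 4:
                    sub = H[j - 1] + reward
                else:
                    sub = H[j - 1] + penalty
            f = NEG
            if lo <= j <= hi:
                if H[j] > NEG and H[j] - go_ge > f:
                    f = H[j] - go_ge
                if F[j] > NEG and F[j] - gap_extend > f:
                    f = F[j] - gap_extend
            if j == 0:
                v = -(go_ge + gap_extend * (i - 1))  # leading query gap
                if v > sub:
                    sub = v
            h = sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < cutoff:
                h = NEG
            Hn[j] = h
            Fn[j] = f
            if h > NEG:
                if new_lo < 0:
                    new_lo = j
                new_hi = j
                if h > best:
                    best = h
                    bi = i
                    bj = j
            ne = e - gap_extend
            if h > NEG and h - go_ge > ne:
                ne = h - go_ge
            e = ne
            if j >= hi + 2 and e < cutoff:
                break
            j += 1
        if new_lo < 0:
            break
        lo = new_lo
        hi = new_hi
        H, Hn = Hn, H
        F, Fn = Fn, F
    return best, bi, bj


@njit(cache=True)
def banded_global_stats(q, s, reward, penalty, gap_open, gap_extend,
                        band_lo, band_hi):
    """Global affine alignment of q vs s inside a diagonal band, with stats.

    The band restricts ``j - i`` to ``[band_lo, band_hi]`` and must contain
    both (0, 0) and (len(q), len(s)).  Returns
    ``(score, matches, mismatches, gap_cols, gap_opens, aligned_cols)``
    for one deterministic optimal path (ties prefer diagonal steps, then
    gaps consuming the subject, then gaps consuming the query).
    """
    m, n = len(q), len(s)
    W = band_hi - band_lo + 1
    go_ge = gap_open + gap_extend
    H = np.full((m + 1, W), NEG, dtype=np.int64)
    E = np.full((m + 1, W), NEG, dtype=np.int64)
    F = np.full((m + 1, W), NEG, dtype=np.int64)

    for i in range(m + 1):
        jlo = i + band_lo
        if jlo < 0:
            jlo = 0
        jhi = i + band_hi
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            w = j - i - band_lo
            if i == 0 and j == 0:
                H[0, w] = 0
                continue
            e = NEG
            if j > 0 and w - 1 >= 0:
                hw = H[i, w - 1]
                ew = E[i, w - 1]
                if hw > NEG and hw - go_ge > e:
                    e = hw - go_ge
                if ew > NEG and ew - gap_extend > e:
                    e = ew - gap_extend
            f = NEG
            if i > 0 and w + 1 < W:
                hv = H[i - 1, w + 1]
                fv = F[i - 1, w + 1]
                if hv > NEG and hv - go_ge > f:
                    f = hv - go_ge
                if fv > NEG and fv - gap_extend > f:
                    f = fv - gap_extend
            d = NEG
            if i > 0 and j > 0:
                hp = H[i - 1, w]
                if hp > NEG:
                    if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                        d = hp + reward
                    else:
                        d = hp + penalty
            E[i, w] = e
            F[i, w] = f
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, w] = h

    wend = n - m - band_lo
    score = H[m, wend]

    matches = 0
    mismatches = 0
    gap_cols = 0
    gap_opens = 0
    cols = 0
    i = m
    j = n
    state = 0  # 0 = H, 1 = E (gap consuming subject), 2 = F (gap consuming query)
    while i > 0 or j > 0:
        w = j - i - band_lo
        if state == 0:
            d = NEG
            ismatch = False
            if i > 0 and j > 0 and H[i - 1, w] > NEG:
                ismatch = q[i - 1] == s[j - 1] and q[i - 1] < 4
                d = H[i - 1, w] + (reward if ismatch else penalty)
            if d > NEG and H[i, w] == d:
                if ismatch:
                    matches += 1
                else:
                    mismatches += 1
                cols += 1
                i -= 1
                j -= 1
            elif H[i, w] == E[i, w]:
                state = 1
            else:
                state = 2
        elif state == 1:
            gap_cols += 1
            cols += 1
            ew = E[i, w - 1] if w - 1 >= 0 else NEG
            if ew > NEG and E[i, w] == ew - gap_extend:
                j -= 1
            else:
                gap_opens += 1
                j -= 1
                state = 0
        else:
            gap_cols += 1
            cols += 1
            fv = F[i - 1, w + 1] if w + 1 < W else NEG
            if fv > NEG and F[i, w] == fv - gap_extend:
                i -= 1
            else:
                gap_opens += 1
                i -= 1
                state = 0
    return score, matches, mismatches, gap_cols, gap_opens, cols
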