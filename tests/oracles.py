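"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — full dynamic programming matrices,
boolean coverage masks, sliding-window scans — and shares no code with the
package's optimized paths.
"""

from __future__ import annotations

import math

import numpy as np


def swg_local(q, s, reward=2, penalty=-3, gap_open=5, gap_extend=2):
    """Full Smith–Waterman–Gotoh local alignment.

    *q* and *s* are integer code arrays.  Returns ``(best_score, path)``
    where *path* is the list of (i, j) 1-based cells aligned diagonally on
    one optimal traceback.
    """
    m, n = len(q), len(s)
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - gap_open - gap_extend)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - gap_open - gap_extend)
            d = H[i - 1, j - 1] + (reward if q[i - 1] == s[j - 1] else penalty)
            H[i, j] = max(0, d, E[i, j], F[i, j])
            if H[i, j] > best:
                best, bi, bj = int(H[i, j]), i, j
    path = []
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            d = H[i - 1, j - 1] + (reward if q[i - 1] == s[j - 1] else penalty)
            if H[i, j] == d:
                path.append((i, j))
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
            else:
                j -= 1
                state = 0
        else:
            if F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
            else:
                i -= 1
                state = 0
    return best, path


def solve_lambda_bisect(reward, penalty, p_match=0.25, tol=1e-12):
    """Bisection root of p e^(lam r) + (1-p) e^(lam pen) = 1 on (0, 10)."""
    f = lambda lam: (p_match * math.exp(lam * reward)
                     + (1 - p_match) * math.exp(lam * penalty) - 1.0)
    lo, hi = 1e-9, 10.0
    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def mask_merge(intervals, min_gap=0):
    """Merge via an explicit boolean mask; returns [(chrom, start, end)]."""
    out = []
    chroms = sorted({iv.chrom for iv in intervals})
    for chrom in chroms:
        ivs = [iv for iv in intervals if iv.chrom == chrom]
        hi = max(iv.end for iv in ivs) + min_gap + 2
        mask = np.zeros(hi, dtype=bool)
        for iv in ivs:
            mask[iv.start: iv.end] = True
        if min_gap > 0:  # bridge gaps strictly smaller than min_gap
            run = 0
            for p in range(hi):
                if mask[p]:
                    if 0 < run < min_gap:
                        mask[p - run: p] = True
                    run = 0
                else:
                    run += 1
        d = np.diff(mask.astype(np.int8))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if mask[0]:
            starts.insert(0, 0)
        if mask[-1]:
            ends.append(hi)
        out.extend((chrom, int(a), int(b)) for a, b in zip(starts, ends))
    return out


def mask_intersection_length(a, b):
    """Shared bases between two interval lists via boolean masks."""
    total = 0
    chroms = {iv.chrom for iv in a} & {iv.chrom for iv in b}
    for chrom in chroms:
        xs = [iv for iv in a if iv.chrom == chrom]
        ys = [iv for iv in b if iv.chrom == chrom]
        hi = max(iv.end for iv in xs + ys) + 1
        ma = np.zeros(hi, dtype=bool)
        mb = np.zeros(hi, dtype=bool)
        for iv in xs:
            ma[iv.start: iv.end] = True
        for iv in ys:
            mb[iv.start: iv.end] = True
        total += int((ma & mb).sum())
    return total


def naive_kmer_scan(kmers, seq, k, max_mismatch=0):
    """All distinct (k-mer, position) placements by direct window comparison.

    Exact mode compares each window string (and its reverse complement)
    against the k-mer set directly; mismatch mode Hamming-compares every
    k-mer at every window.
    """
    comp = str.maketrans("ACGT", "TGCA")
    kmers = set(kmers)
    hits = set()
    for p in range(len(seq) - k + 1):
        window = seq[p: p + k]
        if any(b not in "ACGT" for b in window):
            continue
        rc = window.translate(comp)[::-1]
        if max_mismatch == 0:
            if window in kmers:
                hits.add((window, p))
            if rc in kmers:
                hits.add((rc, p))
            continue
        for km in kmers:
            if sum(a != b for a, b in zip(km, window)) <= max_mismatch:
                hits.add((km, p))
            elif sum(a != b for a, b in zip(km, rc)) <= max_mismatch:
                hits.add((km, p))
    return hits


def naive_seed_scan(q, s, word):
    """All maximal exact forward matches >= word, by direct comparison."""
    matches = set()
    for i in range(len(q) - word + 1):
        for j in range(len(s) - word + 1):
            if q[i: i + word] == s[j: j + word]:
                matches.add((i, j))
    runs = set()
    for (i, j) in matches:
        if (i - 1, j - 1) in matches:
            continue
        L = word
        while (i + L - word + 1, j + L - word + 1) in matches:
            L += 1
        runs.add((i, j, L))
    return runs


def circular_low_runs(cov, thresh, min_run):
    """Maximal circular runs of cov <= thresh, 1-based inclusive bounds."""
    n = len(cov)
    low = [c <= thresh for c in cov]
    if all(low):
        return [(1, n)]
    runs = []
    p = 0
    while p < n:
        if low[p] and not low[(p - 1) % n]:
            L = 0
            while low[(p + L) % n]:
                L += 1
            if L >= min_run:
                runs.append((p + 1, (p + L - 1) % n + 1))
        p += 1
    return sorted(runs)
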