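"""Karlin–Altschul statistics for match/mismatch local-alignment scoring.

The expectation value of a local alignment score ``S`` in a search of a
query of length ``m`` against a subject of length ``n`` is

    E = K * m * n * exp(-lambda * S)

where ``lambda`` is the unique positive root of sum_ij p_i p_j
exp(lambda * s(i, j)) = 1 and ``K`` is a scale constant computed from the
score distribution.  Both depend only on the scoring scheme and the
background base composition.  For the gapped scheme actually used for NUMT
discovery (reward +2, mismatch −3, gap open 5, gap extend 2) the gapped
pair (lambda, K) is shipped as constants mirroring blastn's published
gapped table; any other scheme falls back to the computed ungapped pair
with a warning, which only shifts e-values by a modest constant factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import exp, gcd, log

import numpy as np
from scipy.optimize import brentq

log_ = logging.getLogger(__name__)

UNIFORM_FREQS = (0.25, 0.25, 0.25, 0.25)

#: Gapped (lambda, K) constants for supported (reward, penalty, open, extend)
#: schemes, mirroring blastn's published gapped parameter table.
GAPPED_TABLE: dict[tuple[int, int, int, int], tuple[float, float]] = {
    (2, -3, 5, 2): (0.625, 0.41),
}

LAMBDA_RESIDUAL_TOL = 1e-9


def _match_prob(freqs) -> float:
    p = np.asarray(freqs, dtype=float)
    if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("freqs must be 4 non-negative values summing to 1")
    return float((p * p).sum())


def solve_lambda(reward: int, penalty: int, freqs=UNIFORM_FREQS) -> float:
    """Unique positive root of ``p_m e^(lam*reward) + p_x e^(lam*penalty) = 1``.

    ``p_m`` is the probability that two random bases match under *freqs*.
    Raises ``ValueError`` when the expected pair score is non-negative (no
    positive root exists).
    """
    if reward <= 0 or penalty >= 0:
        raise ValueError("need reward > 0 and penalty < 0")
    pm = _match_prob(freqs)
    expected = pm * reward + (1.0 - pm) * penalty
    if expected >= 0:
        raise ValueError(
            f"expected pair score {expected:.4f} is non-negative; "
            "Karlin-Altschul statistics are undefined"
        )

    def f(lam: float) -> float:
        return pm * exp(lam * reward) + (1.0 - pm) * exp(lam * penalty) - 1.0

    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
    lam = brentq(f, 1e-12, hi, xtol=1e-16, rtol=8.9e-16)
    assert abs(f(lam)) < LAMBDA_RESIDUAL_TOL
    return float(lam)


def entropy_h(reward: int, penalty: int, lam: float, freqs=UNIFORM_FREQS) -> float:
    """Relative entropy H (nats per aligned pair) of the induced alignment."""
    pm = _match_prob(freqs)
    return lam * (
        pm * reward * exp(lam * reward)
        + (1.0 - pm) * penalty * exp(lam * penalty)
    )


def karlin_k(
    reward: int,
    penalty: int,
    freqs=UNIFORM_FREQS,
    lam: float | None = None,
    rel_tol: float = 1e-6,
    max_terms: int = 1000,
) -> float:
    """Karlin–Altschul K for an ungapped match/mismatch scheme.

    Computed by the standard lattice series: with S_j the j-step random walk
    of pair scores,

        sigma = sum_j (1/j) [ P(S_j >= 0) + E(e^(lam S_j); S_j < 0) ]
        K     = d * lam * e^(-2 sigma) / (H * (1 - e^(-lam d)))

    where ``d`` is the score lattice period.  The series is truncated when a
    term's relative contribution falls below *rel_tol*.  Reproduces blastn's
    published ungapped constants (e.g. 0.408 for +2/−3 at uniform
    composition).
    """
    if lam is None:
        lam = solve_lambda(reward, penalty, freqs)
    pm = _match_prob(freqs)
    lo, hi = penalty, reward
    step = np.zeros(hi - lo + 1)
    step[reward - lo] = pm
    step[penalty - lo] = 1.0 - pm
    d = gcd(abs(reward), abs(penalty))
    H = entropy_h(reward, penalty, lam, freqs)

    sigma = 0.0
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(1, max_terms + 1):
        cur = np.convolve(cur, step)
        cur_lo += lo
        scores = np.arange(cur_lo, cur_lo + len(cur))
        neg = scores < 0
        term = float((cur[neg] * np.exp(lam * scores[neg])).sum() + cur[~neg].sum())
        sigma += term / j
        if j > 8 and term / j < rel_tol * sigma:
            break
    return d * lam * exp(-2.0 * sigma) / (H * (1.0 - exp(-lam * d)))


@dataclass
class ScoringScheme:
    """Local-alignment scoring parameters plus their (lambda, K) statistics.

    Gap cost for a gap of length L is ``gap_open + gap_extend * L``.
    """

    reward: int = 2
    penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    freqs: tuple[float, float, float, float] = UNIFORM_FREQS
    lambda_: float = field(default=0.0)
    K: float = field(default=0.0)
    source: str = field(default="")

    def __post_init__(self) -> None:
        if self.reward <= 0 or self.penalty >= 0:
            raise ValueError("need reward > 0 and penalty < 0")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("need gap_open >= 0 and gap_extend > 0")
        if not self.source:
            key = (self.reward, self.penalty, self.gap_open, self.gap_extend)
            if key in GAPPED_TABLE and self.freqs == UNIFORM_FREQS:
                self.lambda_, self.K = GAPPED_TABLE[key]
                self.source = "table-gapped"
            else:
                self.lambda_ = solve_lambda(self.reward, self.penalty, self.freqs)
                self.K = karlin_k(self.reward, self.penalty, self.freqs, self.lambda_)
                self.source = "computed-ungapped"
                log_.warning(
                    "no gapped (lambda, K) table entry for scheme %s; "
                    "using computed ungapped values lambda=%.4f K=%.4f",
                    key, self.lambda_, self.K,
                )
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def evalue(self, score: float, m: int, n: int) -> float:
        """Expected chance hits scoring >= *score* in an m x n search."""
        return evalue(score, m, n, self)

    def score_cutoff(self, max_evalue: float, m: int, n: int) -> float:
        """Smallest score whose e-value is <= *max_evalue* (closed form)."""
        return log(self.K * m * n / max_evalue) / self.lambda_


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation ``K * m * n * exp(-lambda * score)``."""
    if m <= 0 or n <= 0:
        raise ValueError("search lengths m and n must be positive")
    return scheme.K * m * n * exp(-scheme.lambda_ * score)
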