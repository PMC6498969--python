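"""Nonparametric and parametric statistics for paired rating contrasts.

Everything here operates on within-participant difference scores or on the
counts of participants whose difference is positive, tied, or negative, which
is all the two-condition repeated-measures tests need.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "friedman_two_conditions",
    "two_proportion_z",
    "paired_t_and_d",
    "bic_bayes_factor",
]


def friedman_two_conditions(n_first_higher: int, n_tied: int, n_second_higher: int) -> float:
    """Two-condition Friedman χ²r from paired sign counts, ties mid-ranked.

    Within each participant the higher condition gets rank 2, the lower rank
    1, and a tie gives each condition rank 1.5.  With column rank sums R1 and
    R2 over N participants and k = 2 conditions,

        χ²r = 12 / (N·k·(k+1)) · (R1² + R2²) − 3·N·(k+1).

    No tie-correction denominator is applied.
    """
    if min(n_first_higher, n_tied, n_second_higher) < 0:
        raise ValueError("counts must be non-negative")
    n = n_first_higher + n_tied + n_second_higher
    if n < 1:
        raise ValueError("at least one participant is required")
    r1 = 2.0 * n_first_higher + 1.5 * n_tied + 1.0 * n_second_higher
    r2 = 1.0 * n_first_higher + 1.5 * n_tied + 2.0 * n_second_higher
    return 12.0 / (n * 2 * 3) * (r1**2 + r2**2) - 3.0 * n * 3


def two_proportion_z(k1: int, k2: int, n: int) -> float:
    """Pooled two-proportion z statistic for equal group sizes.

    z = (k1/n − k2/n) / sqrt(p̂(1−p̂)·2/n) with p̂ = (k1+k2)/(2n).
    Undefined (raises) when the pooled proportion is 0 or 1.
    """
    if n <= 0:
        raise ValueError("group size must be positive")
    if not (0 <= k1 <= n and 0 <= k2 <= n):
        raise ValueError("counts must lie in [0, n]")
    p = (k1 + k2) / (2.0 * n)
    if p in (0.0, 1.0):
        raise ZeroDivisionError("pooled proportion is degenerate (0 or 1)")
    return (k1 / n - k2 / n) / math.sqrt(p * (1 - p) * 2.0 / n)


def paired_t_and_d(differences) -> tuple[float, int, float]:
    """Paired t, degrees of freedom, and Cohen's d from difference scores.

    d is the standardized mean difference mean/sd, equivalently t/√N.
    """
    x = np.asarray(differences, dtype=float)
    if x.size < 2:
        raise ValueError("at least two difference scores are required")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("difference scores have zero variance")
    n = x.size
    t = x.mean() / (sd / math.sqrt(n))
    return float(t), n - 1, float(x.mean() / sd)


def bic_bayes_factor(t: float, n: int) -> float:
    """Unit-information (BIC) approximation to BF10 for a paired t statistic.

    BF10 ≈ exp(ΔBIC/2) with ΔBIC = n·ln(1/(1−R²)) − ln n and
    R² = t²/(t² + n − 1).  This is the standard BIC approximation; it is
    known to track the order of magnitude of unit-information Bayes factors
    rather than reproduce any particular software's value exactly.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    r2 = t * t / (t * t + n - 1)
    delta_bic = n * math.log(1.0 / (1.0 - r2)) - math.log(n)
    return math.exp(delta_bic / 2.0)
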