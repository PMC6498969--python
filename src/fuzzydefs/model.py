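"""Core multiple-definitions model of fuzzy category membership.

A fuzzy one-dimensional concept such as *middle-age* is represented not by a
membership function but by a population of crisp *definitions*, each a closed
interval of ages (e.g. "from 42 to 54").  Graded truth arises from sampling:
the truth of "a person is middle-aged at X" is the proportion of sampled
definitions that contain X; a conjunction requires every listed age to fall in
the definition, a disjunction at least one.  Because each definition is a
contiguous range, this predicts the *distance effect* — conjunctions of nearby
ages are truer than conjunctions of remote ages with identical constituent
truths, and the reverse for disjunctions — which no rule that computes a
compound's truth from its constituents' truths alone can produce.

The module provides

* interval sampling from a Gaussian (center, width) generative distribution,
* truth evaluation for simple statements, conjunctions and disjunctions,
  optionally with the contraction–expansion adjustment (conjunctions widen
  each sampled definition by a fixed number of years per end, disjunctions
  shrink it),
* an exact numerical-integration oracle for the expected truth under the
  generative distribution,
* the three competing truth-functional composition rules (product, min/max,
  averaging), and
* the point-definition variant in which each sampled definition is a single
  age and truth decays with distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "AgeInterval",
    "DefinitionDistribution",
    "ConnectiveAdjustment",
    "NO_ADJUSTMENT",
    "MAX_WIDTH_RESAMPLES",
    "sample_definition",
    "sample_definitions",
    "sample_widths",
    "adjust_interval",
    "truth_simple",
    "truth_conjunction",
    "truth_disjunction",
    "expected_truth",
    "truth_point_model",
    "rule_product",
    "rule_minmax",
    "rule_averaging",
]

Mode = Literal["simple", "conjunction", "disjunction"]

#: Cap on rejection-sampling passes for non-negative widths.  Exceeding it
#: indicates a configuration where essentially all probability mass of the
#: width distribution is negative, which is treated as a user error.
MAX_WIDTH_RESAMPLES = 1000


@dataclass(frozen=True)
class AgeInterval:
    """One crisp definition: a closed range of ages, possibly empty.

    The interval is empty iff ``lower > upper``; an empty interval contains
    no age.  Containment is closed on both ends.
    """

    lower: float
    upper: float

    @property
    def is_empty(self) -> bool:
        return self.lower > self.upper

    @property
    def width(self) -> float:
        return 0.0 if self.is_empty else self.upper - self.lower

    def contains(self, age: float) -> bool:
        return self.lower <= age <= self.upper


@dataclass(frozen=True)
class DefinitionDistribution:
    """Generative parameters for definitions.

    Centers are Normal(center_mean, center_sd); widths are
    Normal(width_mean, width_sd) resampled until non-negative, so the
    realised width distribution is the normal truncated at zero.
    """

    center_mean: float
    center_sd: float
    width_mean: float
    width_sd: float

    def __post_init__(self) -> None:
        if self.center_sd < 0 or self.width_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.width_mean <= 0:
            raise ValueError("width_mean must be positive")


@dataclass(frozen=True)
class ConnectiveAdjustment:
    """Contraction–expansion factors, in years applied to each end.

    ``expansion_years`` widens every sampled definition when a conjunction is
    evaluated; ``contraction_years`` shrinks it for disjunctions.  Both zero
    recovers the pure multiple-definitions model.
    """

    expansion_years: float = 0.0
    contraction_years: float = 0.0

    def __post_init__(self) -> None:
        if self.expansion_years < 0 or self.contraction_years < 0:
            raise ValueError("adjustment factors must be non-negative")

    @classmethod
    def symmetric(cls, ec_factor: float) -> "ConnectiveAdjustment":
        """The simulation's single expansion–contraction factor."""
        return cls(expansion_years=ec_factor, contraction_years=ec_factor)


NO_ADJUSTMENT = ConnectiveAdjustment()


# ---------------------------------------------------------------------------
# Sampling


def sample_widths(dist: DefinitionDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` non-negative widths by rejection from the normal."""
    w = rng.normal(dist.width_mean, dist.width_sd, size=n)
    if dist.width_sd == 0:
        return w
    for _ in range(MAX_WIDTH_RESAMPLES):
        bad = w < 0
        if not bad.any():
            return w
        w[bad] = rng.normal(dist.width_mean, dist.width_sd, size=int(bad.sum()))
    raise RuntimeError(
        "width resampling did not terminate; width distribution is almost "
        "entirely negative — check width_mean/width_sd"
    )


def sample_definitions(
    dist: DefinitionDistribution, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` definitions; returns (lower, upper) arrays."""
    c = rng.normal(dist.center_mean, dist.center_sd, size=n)
    w = sample_widths(dist, n, rng)
    return c - w / 2.0, c + w / 2.0


def sample_definition(dist: DefinitionDistribution, rng: np.random.Generator) -> AgeInterval:
    lo, hi = sample_definitions(dist, 1, rng)
    return AgeInterval(float(lo[0]), float(hi[0]))


# ---------------------------------------------------------------------------
# Truth evaluation


def adjust_interval(interval: AgeInterval, delta: float) -> AgeInterval:
    """Expand (``delta > 0``) or contract (``delta < 0``) by |delta| years per end.

    Contraction may consume the whole interval, yielding an empty interval
    that contains no age.
    """
    return AgeInterval(interval.lower - delta, interval.upper + delta)


def _as_bounds(definitions) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(definitions, tuple) and len(definitions) == 2 and isinstance(definitions[0], np.ndarray):
        lo, hi = definitions
    else:
        seq = list(definitions)
        if seq and isinstance(seq[0], AgeInterval):
            lo = np.array([d.lower for d in seq], dtype=float)
            hi = np.array([d.upper for d in seq], dtype=float)
        else:
            arr = np.asarray(seq, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("definitions must be AgeIntervals, (lower, upper) arrays, or an (n, 2) array")
            lo, hi = arr[:, 0], arr[:, 1]
    if lo.size == 0:
        raise ValueError("at least one definition is required")
    return lo, hi


def truth_simple(definitions, age: float) -> float:
    """Proportion of definitions containing ``age`` (closed containment)."""
    lo, hi = _as_bounds(definitions)
    return float(np.mean((lo <= age) & (age <= hi)))


def truth_conjunction(
    definitions, ages: Sequence[float], adjustment: ConnectiveAdjustment = NO_ADJUSTMENT
) -> float:
    """Proportion of (expanded) definitions containing every listed age.

    A contiguous interval contains every age iff it contains the youngest and
    the oldest, so only the extremes are checked.
    """
    if len(ages) == 0:
        raise ValueError("at least one age is required")
    lo, hi = _as_bounds(definitions)
    e = adjustment.expansion_years
    amin, amax = min(ages), max(ages)
    return float(np.mean((lo - e <= amin) & (amax <= hi + e)))


def truth_disjunction(
    definitions, ages: Sequence[float], adjustment: ConnectiveAdjustment = NO_ADJUSTMENT
) -> float:
    """Proportion of (contracted) definitions containing at least one age."""
    if len(ages) == 0:
        raise ValueError("at least one age is required")
    lo, hi = _as_bounds(definitions)
    k = adjustment.contraction_years
    lo2, hi2 = lo + k, hi - k  # empty contracted intervals contain nothing
    hit = np.zeros(lo.shape, dtype=bool)
    for a in ages:
        hit |= (lo2 <= a) & (a <= hi2)
    return float(np.mean(hit))


# ---------------------------------------------------------------------------
# Analytic oracle


def _prob_center_in_union(intervals: list[tuple[float, float]], cm: float, cs: float) -> float:
    """P(center in union of intervals) for center ~ Normal(cm, cs)."""
    ivs = sorted((a, b) for a, b in intervals if a <= b)
    merged: list[list[float]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    if cs == 0:
        return float(any(a <= cm <= b for a, b in merged))
    return float(sum(stats.norm.cdf(b, cm, cs) - stats.norm.cdf(a, cm, cs) for a, b in merged))


def expected_truth(
    dist: DefinitionDistribution,
    ages: Sequence[float],
    mode: Mode = "simple",
    adjustment: ConnectiveAdjustment = NO_ADJUSTMENT,
) -> float:
    """Probability that one sampled definition satisfies the statement.

    Integrates over the width distribution (normal truncated at zero) the
    conditional probability, given the width, that the center falls where the
    statement holds.  Serves as the exact oracle for Monte-Carlo truth
    estimates.
    """
    if len(ages) == 0:
        raise ValueError("at least one age is required")
    if mode == "simple" and len(ages) != 1:
        raise ValueError("simple statements take exactly one age")
    amin, amax = min(ages), max(ages)
    cm, cs = dist.center_mean, dist.center_sd

    if mode in ("simple", "conjunction"):
        e = adjustment.expansion_years if mode == "conjunction" else 0.0

        def prob_given_width(w: float) -> float:
            h = w / 2.0 + e
            # center must lie in [amax - h, amin + h]
            return _prob_center_in_union([(amax - h, amin + h)], cm, cs)

        # the center-interval becomes non-degenerate at this width
        breakpoints = [max(0.0, (amax - amin) - 2 * e)]
    else:
        k = adjustment.contraction_years

        def prob_given_width(w: float) -> float:
            h = w / 2.0 - k
            if h < 0:
                return 0.0
            return _prob_center_in_union([(a - h, a + h) for a in ages], cm, cs)

        srt = sorted(ages)
        breakpoints = [2 * k] + [(b - a) + 2 * k for a, b in zip(srt, srt[1:])]

    if dist.width_sd == 0:
        return prob_given_width(dist.width_mean)

    wdist = stats.truncnorm(
        -dist.width_mean / dist.width_sd, np.inf, loc=dist.width_mean, scale=dist.width_sd
    )
    hi = dist.width_mean + 10 * dist.width_sd
    pts = sorted({p for p in breakpoints if 0 < p < hi})
    val, err = integrate.quad(
        lambda w: prob_given_width(w) * wdist.pdf(w), 0.0, hi, points=pts or None, limit=200
    )
    if not np.isfinite(val) or err > 1e-6 + 1e-4 * abs(val):
        raise ArithmeticError(f"expected_truth integration did not converge (err={err})")
    return float(min(1.0, max(0.0, val)))


# ---------------------------------------------------------------------------
# Point-definition variant


def truth_point_model(points: Iterable[float], ages: Sequence[float], mode: Mode = "simple") -> float:
    """Score of a statement under the point-definition variant.

    Each sampled definition is a single age.  The mean distance D of the
    statement's ages to the sampled points is turned into a bounded score
    1/(1+D): simple — mean |X - p|; conjunction — mean over points of the mean
    of each listed age's distance; disjunction — mean over points of the
    minimum distance.  Only the ordinal behaviour of the score is meaningful.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.size == 0:
        raise ValueError("at least one point definition is required")
    if len(ages) == 0:
        raise ValueError("at least one age is required")
    dist_matrix = np.abs(np.subtract.outer(np.asarray(ages, dtype=float), pts))  # (ages, points)
    if mode == "simple":
        if len(ages) != 1:
            raise ValueError("simple statements take exactly one age")
        d = dist_matrix[0].mean()
    elif mode == "conjunction":
        d = dist_matrix.mean(axis=0).mean()
    elif mode == "disjunction":
        d = dist_matrix.min(axis=0).mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 1.0 / (1.0 + float(d))


# ---------------------------------------------------------------------------
# Truth-functional composition rules (the competitors)


def _check_unit(*values: float) -> None:
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"truth values must lie in [0, 1]; got {v}")


def rule_product(tx: float, ty: float, mode: Literal["conjunction", "disjunction"]) -> float:
    """Product rule: t(X∧Y) = t(X)t(Y); t(X∨Y) = t(X)+t(Y)−t(X)t(Y)."""
    _check_unit(tx, ty)
    return tx * ty if mode == "conjunction" else tx + ty - tx * ty


def rule_minmax(tx: float, ty: float, mode: Literal["conjunction", "disjunction"]) -> float:
    """Min/max rule: conjunction → min, disjunction → max."""
    _check_unit(tx, ty)
    return min(tx, ty) if mode == "conjunction" else max(tx, ty)


def rule_averaging(tx: float, ty: float, mode: Literal["conjunction", "disjunction"]) -> float:
    """Averaging rule: both connectives → the mean of the constituent truths."""
    _check_unit(tx, ty)
    if mode not in ("conjunction", "disjunction"):
        raise ValueError(f"unknown mode {mode!r}")
    return (tx + ty) / 2.0
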