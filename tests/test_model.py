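"""Interval model: sampling, truth evaluation, adjustment, rules, oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzydefs.model import (
    AgeInterval,
    ConnectiveAdjustment,
    DefinitionDistribution,
    NO_ADJUSTMENT,
    adjust_interval,
    expected_truth,
    rule_averaging,
    rule_minmax,
    rule_product,
    sample_definition,
    sample_definitions,
    truth_conjunction,
    truth_disjunction,
    truth_point_model,
    truth_simple,
)

INTRO_DEFS = [AgeInterval(42, 54), AgeInterval(44, 62)]


# ---------------------------------------------------------------------------
# Deterministic truth evaluation


@pytest.mark.parametrize(
    "age, expected",
    [(45, 1.0), (60, 0.5), (30, 0.0), (42, 0.5), (54, 1.0), (62, 0.5)],  # closed endpoints
)
def test_truth_simple_containment_proportion(age, expected):
    assert truth_simple(INTRO_DEFS, age) == expected


@pytest.mark.parametrize(
    "fn, ages, adj, expected",
    [
        (truth_conjunction, (45, 60), NO_ADJUSTMENT, 0.5),
        (truth_conjunction, (35, 60), NO_ADJUSTMENT, 0.0),
        (truth_disjunction, (45, 60), NO_ADJUSTMENT, 1.0),
        (truth_disjunction, (30, 41), NO_ADJUSTMENT, 0.0),
    ],
)
def test_compound_truth_examples(fn, ages, adj, expected):
    assert fn(INTRO_DEFS, ages, adj) == expected


def test_expansion_and_contraction_change_compound_truths():
    one = [AgeInterval(42, 54)]
    assert truth_conjunction(one, (41, 55), ConnectiveAdjustment(expansion_years=1)) == 1.0
    assert truth_conjunction(one, (41, 55)) == 0.0
    assert truth_disjunction(one, (43, 70), ConnectiveAdjustment(contraction_years=2)) == 0.0
    assert truth_disjunction(one, (43, 70)) == 1.0


def test_adjust_interval_per_end():
    assert adjust_interval(AgeInterval(39, 51), 1) == AgeInterval(38, 52)
    assert adjust_interval(AgeInterval(39, 51), -1) == AgeInterval(40, 50)
    shrunk = adjust_interval(AgeInterval(44, 46), -2)
    assert shrunk.is_empty and not shrunk.contains(45)


def test_empty_interval_contains_nothing_and_inputs_validated():
    assert AgeInterval(50, 40).is_empty
    assert truth_simple([AgeInterval(50, 40), AgeInterval(40, 50)], 45) == 0.5
    with pytest.raises(ValueError):
        truth_simple([], 45)
    with pytest.raises(ValueError):
        truth_conjunction(INTRO_DEFS, ())
    with pytest.raises(ValueError):
        ConnectiveAdjustment(expansion_years=-1)


# ---------------------------------------------------------------------------
# Sampling


def test_degenerate_distribution_is_deterministic():
    dist = DefinitionDistribution(45, 0.0, 10, 0.0)
    rng = np.random.default_rng(0)
    for _ in range(5):
        iv = sample_definition(dist, rng)
        assert (iv.lower, iv.upper) == (40.0, 50.0)


def test_sampled_widths_nonnegative_and_truncation_inflates_mean():
    dist = DefinitionDistribution(45, 5, 12, 6)
    rng = np.random.default_rng(42)
    lo, hi = sample_definitions(dist, 100_000, rng)
    assert (lo <= hi).all()
    mid, width = (lo + hi) / 2, hi - lo
    assert abs(mid.mean() - 45) < 0.1
    # mean of a normal truncated at 0: mu + sigma * phi(a) / (1 - Phi(a)), a = -mu/sigma
    a = -dist.width_mean / dist.width_sd
    phi = math.exp(-a * a / 2) / math.sqrt(2 * math.pi)
    from scipy.stats import norm

    expected_mean = dist.width_mean + dist.width_sd * phi / (1 - norm.cdf(a))
    assert width.mean() >= dist.width_mean
    assert abs(width.mean() - expected_mean) < 0.1


def test_high_variance_widths_stay_nonnegative():
    # width SD equal to the mean: ~16% of raw draws are negative and resampled
    dist = DefinitionDistribution(45, 5, 10, 10)
    lo, hi = sample_definitions(dist, 50_000, np.random.default_rng(3))
    assert (hi >= lo).all()


# ---------------------------------------------------------------------------
# Analytic oracle and Monte-Carlo agreement


def test_expected_truth_degenerate_and_closed_form():
    crisp = DefinitionDistribution(45, 0.0, 10, 0.0)
    assert expected_truth(crisp, [50], "simple") == 1.0
    assert expected_truth(crisp, [51], "simple") == 0.0
    gauss = DefinitionDistribution(45, 5, 12, 0.0)
    # P(|45 - c| <= 6) for c ~ N(45, 5) = P(|Z| <= 1.2)
    assert expected_truth(gauss, [45], "simple") == pytest.approx(0.76986, abs=1e-4)


@pytest.mark.parametrize(
    "ages, mode, adj",
    [
        ([45], "simple", NO_ADJUSTMENT),
        ([40, 50], "conjunction", NO_ADJUSTMENT),
        ([40, 50], "conjunction", ConnectiveAdjustment(expansion_years=2)),
        ([35, 55], "disjunction", NO_ADJUSTMENT),
        ([35, 55], "disjunction", ConnectiveAdjustment(contraction_years=2)),
        ([33, 45, 57], "conjunction", NO_ADJUSTMENT),
        ([30, 45, 60], "disjunction", ConnectiveAdjustment(contraction_years=1)),
    ],
)
def test_monte_carlo_matches_integration_oracle(ages, mode, adj):
    """Sampled truths agree with numerical integration within 3 binomial SEs."""
    dist = DefinitionDistribution(45, 5, 12, 6)
    n = 100_000
    defs = sample_definitions(dist, n, np.random.default_rng(7))
    mc = {
        "simple": lambda: truth_simple(defs, ages[0]),
        "conjunction": lambda: truth_conjunction(defs, ages, adj),
        "disjunction": lambda: truth_disjunction(defs, ages, adj),
    }[mode]()
    p = expected_truth(dist, ages, mode, adj)
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    assert abs(mc - p) <= 3 * se + 1e-9


# ---------------------------------------------------------------------------
# Point-definition variant


def test_point_model_hand_enumerated_scores():
    assert truth_point_model([45], [45], "simple") == 1.0
    assert truth_point_model([40, 50], [40, 50], "conjunction") == pytest.approx(1 / 6)
    assert truth_point_model([40, 50], [40, 50], "disjunction") == 1.0


def test_point_model_distance_effect_only_for_disjunctions():
    # equal-truth ages 40 and 50 around symmetric points; A = 35 is the outer age
    pts = [40, 50]
    near_conj = truth_point_model(pts, [35, 40], "conjunction")
    far_conj = truth_point_model(pts, [35, 50], "conjunction")
    assert near_conj == pytest.approx(far_conj)  # mean distance identical
    near_disj = truth_point_model(pts, [35, 40], "disjunction")
    far_disj = truth_point_model(pts, [35, 50], "disjunction")
    assert far_disj > near_disj


# ---------------------------------------------------------------------------
# Composition rules


@pytest.mark.parametrize(
    "rule, tx, ty, mode, expected",
    [
        (rule_product, 0.5, 0.5, "conjunction", 0.25),
        (rule_product, 0.5, 0.5, "disjunction", 0.75),
        (rule_product, 1.0, 0.3, "conjunction", 0.3),
        (rule_product, 1.0, 0.3, "disjunction", 1.0),
        (rule_minmax, 0.3, 0.8, "conjunction", 0.3),
        (rule_minmax, 0.3, 0.8, "disjunction", 0.8),
        (rule_averaging, 0.3, 0.8, "conjunction", 0.55),
        (rule_averaging, 0.3, 0.8, "disjunction", 0.55),
    ],
)
def test_rule_values(rule, tx, ty, mode, expected):
    assert rule(tx, ty, mode) == pytest.approx(expected)


@given(t=st.floats(0, 1), u=st.floats(0, 1))
@settings(max_examples=50, derandomize=True)
def test_rule_identities(t, u):
    assert rule_minmax(t, t, "conjunction") == rule_minmax(t, t, "disjunction") == t
    assert rule_averaging(t, u, "conjunction") == rule_averaging(t, u, "disjunction")
    assert rule_product(t, u, "conjunction") <= min(t, u)
    assert rule_product(t, u, "disjunction") >= max(t, u)


def test_rules_reject_out_of_range_truths():
    with pytest.raises(ValueError):
        rule_product(1.2, 0.5, "conjunction")


# ---------------------------------------------------------------------------
# Model invariants (property-based)

interval_sets = st.lists(
    st.tuples(st.floats(0, 90), st.floats(0, 40)).map(lambda t: AgeInterval(t[0], t[0] + t[1])),
    min_size=1,
    max_size=30,
)
age = st.integers(10, 80)


@given(defs=interval_sets, a1=age, a2=age)
@settings(max_examples=200, derandomize=True)
def test_compound_truth_bounds(defs, a1, a2):
    """Conjunctions never exceed the min, disjunctions never fall below the max."""
    t1, t2 = truth_simple(defs, a1), truth_simple(defs, a2)
    assert truth_conjunction(defs, (a1, a2)) <= min(t1, t2)
    assert truth_disjunction(defs, (a1, a2)) >= max(t1, t2)


@given(defs=interval_sets, a=age)
@settings(max_examples=100, derandomize=True)
def test_degenerate_idempotence(defs, a):
    t = truth_simple(defs, a)
    assert truth_conjunction(defs, (a, a)) == t
    assert truth_disjunction(defs, (a, a)) == t


@given(defs=interval_sets, triple=st.tuples(age, age, age))
@settings(max_examples=200, derandomize=True)
def test_outside_set_dominance_and_triple_identity(defs, triple):
    a, x, y = sorted(triple)
    # any definition containing the far pair {a, y} contains the near pair {a, x}
    assert truth_conjunction(defs, (a, x)) >= truth_conjunction(defs, (a, y))
    # the definitions spanning a and y are exactly those spanning a, x, y
    assert truth_conjunction(defs, (a, x, y)) == truth_conjunction(defs, (a, y))


@given(
    base=interval_sets,
    center=st.integers(30, 60),
    d=st.integers(1, 15),
    gap=st.integers(1, 10),
)
@settings(max_examples=200, derandomize=True)
def test_disjunction_distance_inequality_under_equal_counts(base, center, d, gap):
    """With t(X) = t(Y) by mirror symmetry, near disjunctions cannot beat far ones."""
    mirrored = [AgeInterval(2 * center - iv.upper, 2 * center - iv.lower) for iv in base]
    defs = list(base) + mirrored
    x, y = center - d, center + d
    a = x - gap
    assert truth_simple(defs, x) == truth_simple(defs, y)
    assert truth_disjunction(defs, (a, x)) <= truth_disjunction(defs, (a, y))


@given(defs=interval_sets, a1=age, a2=age, e1=st.floats(0, 5), e2=st.floats(0, 5))
@settings(max_examples=100, derandomize=True)
def test_adjustment_monotonicity(defs, a1, a2, e1, e2):
    lo, hi = min(e1, e2), max(e1, e2)
    conj = lambda e: truth_conjunction(defs, (a1, a2), ConnectiveAdjustment(expansion_years=e))
    disj = lambda k: truth_disjunction(defs, (a1, a2), ConnectiveAdjustment(contraction_years=k))
    assert conj(lo) <= conj(hi)
    assert disj(lo) >= disj(hi)
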