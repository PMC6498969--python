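"""Per-participant distance/minimax-effect analysis of truth ratings.

The experimental logic: for each participant, average the three ratings of
each simple age into a truth profile and locate its peak (possibly a
plateau).  Find *equal pairs* — ages X below the peak and Y above it with
exactly equal mean truth.  Pair each member of an equal pair with its
immediate neighbours A in the age sequence to form *near* pairs (A, X) and
corresponding *far* pairs (A, Y): near and far compounds then have identical
constituent truths, so any truth-functional composition rule predicts no
near/far difference.  The multiple-definitions model predicts near
conjunctions truer than far ones and far disjunctions truer than near ones
(the distance effect), and bounds conjunctions by the minimum and
disjunctions by the maximum constituent truth (no minimax effect).

`TruthJudgmentAnalysis` wraps this pipeline statsmodels-style: build it from
a tidy ratings table, call :meth:`fit`, and read per-participant effects,
nonparametric and paired tests, and a text summary off the results object.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as fstats
from .design import StimulusDesign, build_design

__all__ = [
    "PeakRange",
    "TruthProfile",
    "NearFarSet",
    "ParticipantEffects",
    "StrategyLabel",
    "mean_profile",
    "find_peak",
    "find_equal_pairs",
    "build_near_far",
    "participant_effects",
    "classify_strategy",
    "TruthJudgmentAnalysis",
    "TruthJudgmentResults",
    "RATINGS_COLUMNS",
]

RATINGS_COLUMNS = ["participant_id", "kind", "age1", "age2", "age3", "rating", "repetition"]


@dataclass(frozen=True)
class PeakRange:
    """The age(s) with a participant's maximal simple truth, as a closed span."""

    low: int
    high: int

    def contains(self, age: float) -> bool:
        return self.low <= age <= self.high


@dataclass(frozen=True)
class TruthProfile:
    participant_id: object
    mean_by_age: dict[int, float]
    peak: PeakRange


@dataclass(frozen=True)
class NearFarSet:
    """Near/far compound pairs derived from one equal pair.

    ``entries`` holds one tuple per admissible neighbour:
    (third_age, near_pair, far_pair, label) with pairs stored younger-first
    and label 'outside' when the third age lies outside the closed interval
    spanned by the equal pair, 'inside' otherwise.
    """

    equal_pair: tuple[int, int]
    entries: tuple[tuple[int, tuple[int, int], tuple[int, int], str], ...]

    @property
    def near_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(e[1] for e in self.entries)

    @property
    def far_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(e[2] for e in self.entries)


@dataclass(frozen=True)
class ParticipantEffects:
    participant_id: object
    n_equal_pairs: int
    n_near_pairs: int
    near_conj_mean: float
    far_conj_mean: float
    near_disj_mean: float
    far_disj_mean: float
    min_constituent_mean: float
    max_constituent_mean: float

    @property
    def distance_effect_conj(self) -> float:
        return self.near_conj_mean - self.far_conj_mean

    @property
    def distance_effect_disj(self) -> float:
        return self.far_disj_mean - self.near_disj_mean

    @property
    def minimum_effect(self) -> float:
        return self.near_conj_mean - self.min_constituent_mean

    @property
    def maximum_effect(self) -> float:
        return self.max_constituent_mean - self.near_disj_mean

    @property
    def far_minimum_effect(self) -> float:
        return self.far_conj_mean - self.min_constituent_mean

    @property
    def far_maximum_effect(self) -> float:
        return self.max_constituent_mean - self.far_disj_mean


@dataclass(frozen=True)
class StrategyLabel:
    label: str  # "Logical" | "Averaging"
    n_qualifying_triples: int
    triple_mean: float
    double_mean: float


# ---------------------------------------------------------------------------
# Core per-participant steps


def find_peak(mean_by_age: Mapping[int, float]) -> PeakRange:
    """Peak of a truth profile; a plateau spans lowest to highest maximal age."""
    if not mean_by_age:
        raise ValueError("empty truth profile")
    peak_value = max(mean_by_age.values())
    at_max = [a for a, v in mean_by_age.items() if v == peak_value]
    return PeakRange(min(at_max), max(at_max))


def mean_profile(records: pd.DataFrame, design: StimulusDesign | None = None) -> TruthProfile:
    """Average one participant's simple-sentence ratings across repetitions."""
    design = design or build_design("experiment-1")
    simple = records[records["kind"] == "simple"]
    if simple.empty:
        raise ValueError("no simple-sentence records for participant")
    pid = records["participant_id"].iloc[0]
    means = simple.groupby("age1")["rating"].mean()
    missing = set(design.simple_ages) - {int(a) for a in means.index}
    if missing:
        raise ValueError(f"participant {pid!r} is missing simple ratings for ages {sorted(missing)}")
    mean_by_age = {int(a): float(v) for a, v in means.items()}
    return TruthProfile(pid, mean_by_age, find_peak(mean_by_age))


def find_equal_pairs(
    profile: TruthProfile, tol: float = 0.0, floor: float | None = None
) -> list[tuple[int, int]]:
    """All (X, Y) with X below and Y above the peak and equal mean truth.

    Equality is exact by default (means with a shared denominator compare
    exactly in floating point); ``tol`` admits |t(X) − t(Y)| ≤ tol for use
    with noisy simulated truth proportions.  An empty result means the
    participant is excluded from the effect analysis.

    ``floor`` excludes vacuous ties at the bottom of the scale (0 on the
    truth scale, 1 on the 1–6 rating scale): when two ages are tied because
    no sampled definition contains either, every compound built from them is
    equally false and the near/far comparison carries no information about
    how compounds are composed.
    """
    peak = profile.peak
    below = sorted(a for a in profile.mean_by_age if a < peak.low)
    above = sorted(a for a in profile.mean_by_age if a > peak.high)
    out = []
    for x in below:
        for y in above:
            tx, ty = profile.mean_by_age[x], profile.mean_by_age[y]
            equal = (tx == ty) if tol == 0.0 else (abs(tx - ty) <= tol)
            if equal and (floor is None or max(tx, ty) > floor + tol):
                out.append((x, y))
    return out


def _neighbours(age: int, sequence: Sequence[int]) -> list[int]:
    i = sequence.index(age)
    out = []
    if i > 0:
        out.append(sequence[i - 1])
    if i + 1 < len(sequence):
        out.append(sequence[i + 1])
    return out


def build_near_far(
    pair: tuple[int, int],
    peak: PeakRange,
    design: StimulusDesign | None = None,
) -> NearFarSet:
    """Derive the corresponding near/far compound pairs from one equal pair.

    Each member of the equal pair is paired with its immediate neighbours in
    the simple-age sequence, keeping only neighbours that occur in compound
    sentences and are not a peak age.  A neighbour A of X gives near (A, X)
    and far (A, Y); a neighbour B of Y gives near (B, Y) and far (X, B).
    An equal pair with a member outside the compound-age range (15 or 75)
    yields no entries, since no compound sentence involves that member.
    """
    design = design or build_design("experiment-1")
    x, y = pair
    if not (x < peak.low and y > peak.high):
        raise ValueError(f"equal pair {pair} does not straddle the peak {peak}")
    if x not in design.compound_ages or y not in design.compound_ages:
        return NearFarSet(equal_pair=pair, entries=())
    entries = []
    for member, partner in ((x, y), (y, x)):
        for a in _neighbours(member, design.simple_ages):
            if a not in design.compound_ages or peak.contains(a):
                continue
            near = tuple(sorted((a, member)))
            far = tuple(sorted((a, partner)))
            label = "outside" if (a < x or a > y) else "inside"
            entries.append((a, near, far, label))
    return NearFarSet(equal_pair=pair, entries=tuple(entries))


def participant_effects(
    profile: TruthProfile,
    conj_values: Mapping[tuple[int, int], float],
    disj_values: Mapping[tuple[int, int], float],
    sets: Sequence[NearFarSet],
) -> ParticipantEffects | None:
    """Pool near/far compound means and the minimax constituent bounds.

    All near/far pairs from all of the participant's equal-pair sets are
    pooled.  Corresponding near and far pairs share their constituent truth
    multiset by construction, so the min/max constituent means are computed
    once from the near pairs.  Returns None when no set yields any admissible
    near pair.
    """
    near_conj, far_conj, near_disj, far_disj, mins, maxs = [], [], [], [], [], []
    for nf in sets:
        for third, near, far, _label in nf.entries:
            try:
                near_conj.append(conj_values[near])
                far_conj.append(conj_values[far])
                near_disj.append(disj_values[near])
                far_disj.append(disj_values[far])
            except KeyError as exc:  # pragma: no cover - construction bug guard
                raise ValueError(f"compound pair {exc} missing from ratings") from exc
            t_third = profile.mean_by_age[third]
            t_member = profile.mean_by_age[near[0] if near[1] == third else near[1]]
            # identical for the far pair since t(X) = t(Y)
            mins.append(min(t_third, t_member))
            maxs.append(max(t_third, t_member))
    if not near_conj:
        return None
    return ParticipantEffects(
        participant_id=profile.participant_id,
        n_equal_pairs=len(sets),
        n_near_pairs=len(near_conj),
        near_conj_mean=float(np.mean(near_conj)),
        far_conj_mean=float(np.mean(far_conj)),
        near_disj_mean=float(np.mean(near_disj)),
        far_disj_mean=float(np.mean(far_disj)),
        min_constituent_mean=float(np.mean(mins)),
        max_constituent_mean=float(np.mean(maxs)),
    )


def classify_strategy(
    profile: TruthProfile,
    triple_values: Mapping[tuple[int, int, int], float],
    double_values: Mapping[tuple[int, int], float],
) -> StrategyLabel:
    """Logical vs Averaging from triple- vs double-conjunction ratings.

    Qualifying triples (A, B, C) have A < B < C with the middle age strictly
    truer than both outer ages in the simple-statement profile; triples whose
    middle age was never rated as a simple sentence cannot qualify.  Under
    interval sampling t(A∧B∧C) = t(A∧C); under averaging the triple exceeds
    the double.  A strict excess of the triple mean assigns Averaging.
    """
    t = profile.mean_by_age
    triples, doubles = [], []
    for (a, b, c), v in triple_values.items():
        if b not in t:
            continue
        if t[b] > t[a] and t[b] > t[c]:
            triples.append(v)
            doubles.append(double_values[(a, c)])
    n = len(triples)
    triple_mean = float(np.mean(triples)) if n else float("nan")
    double_mean = float(np.mean(doubles)) if n else float("nan")
    label = "Averaging" if n and triple_mean > double_mean else "Logical"
    return StrategyLabel(label, n, triple_mean, double_mean)


# ---------------------------------------------------------------------------
# Model / Results interface


_EFFECT_COLUMNS = [
    "n_equal_pairs",
    "n_near_pairs",
    "near_conj_mean",
    "far_conj_mean",
    "near_disj_mean",
    "far_disj_mean",
    "min_constituent_mean",
    "max_constituent_mean",
    "distance_effect_conj",
    "distance_effect_disj",
    "minimum_effect",
    "maximum_effect",
    "far_minimum_effect",
    "far_maximum_effect",
]


class TruthJudgmentAnalysis:
    """Distance/minimax-effect analysis of a cohort's truth ratings.

    Parameters
    ----------
    data
        Tidy ratings with columns ``participant_id, kind, age1, age2, age3,
        rating, repetition``; kinds are ``simple``, ``conjunction2``,
        ``disjunction`` and, for the second experiment, ``conjunction3``.
    design
        Stimulus design; inferred from the presence of triple conjunctions
        when omitted.
    equal_pair_tol
        Tolerance for the equal-pair truth equality (default exact).
    floor
        Scale floor for excluding vacuous equal pairs (default 1.0, the
        bottom of the 1–6 rating scale; pass None to keep floor ties).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        design: StimulusDesign | None = None,
        equal_pair_tol: float = 0.0,
        floor: float | None = 1.0,
    ):
        missing = set(RATINGS_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"ratings table is missing columns {sorted(missing)}")
        if design is None:
            has_triples = (data["kind"] == "conjunction3").any()
            design = build_design("experiment-2" if has_triples else "experiment-1")
        bad = set(data["kind"].unique()) - {"simple", "conjunction2", "conjunction3", "disjunction"}
        if bad:
            raise ValueError(f"unknown sentence kinds {sorted(bad)}")
        self.data = data
        self.design = design
        self.equal_pair_tol = equal_pair_tol
        self.floor = floor

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TruthJudgmentAnalysis":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "TruthJudgmentResults":
        rows, strategy_rows, excluded = [], [], []
        for pid, grp in self.data.groupby("participant_id", sort=True):
            profile = mean_profile(grp, self.design)
            conj2 = {
                (int(r.age1), int(r.age2)): float(r.rating)
                for r in grp[grp["kind"] == "conjunction2"].itertuples()
            }
            disj = {
                (int(r.age1), int(r.age2)): float(r.rating)
                for r in grp[grp["kind"] == "disjunction"].itertuples()
            }
            if self.design.variant == "experiment-2":
                conj3 = {
                    (int(r.age1), int(r.age2), int(r.age3)): float(r.rating)
                    for r in grp[grp["kind"] == "conjunction3"].itertuples()
                }
                lab = classify_strategy(profile, conj3, conj2)
                strategy_rows.append(
                    {
                        "participant_id": pid,
                        "label": lab.label,
                        "n_qualifying_triples": lab.n_qualifying_triples,
                        "triple_mean": lab.triple_mean,
                        "double_mean": lab.double_mean,
                    }
                )
            pairs = find_equal_pairs(profile, tol=self.equal_pair_tol, floor=self.floor)
            eff = None
            if pairs:
                sets = [build_near_far(p, profile.peak, self.design) for p in pairs]
                eff = participant_effects(profile, conj2, disj, sets)
            if eff is None:
                excluded.append(pid)
                continue
            rows.append(
                {
                    "participant_id": pid,
                    **{c: getattr(eff, c) for c in _EFFECT_COLUMNS},
                }
            )
        effects = pd.DataFrame(rows, columns=["participant_id", *_EFFECT_COLUMNS])
        effects = effects.set_index("participant_id") if len(effects) else effects
        strategies = (
            pd.DataFrame(strategy_rows).set_index("participant_id")
            if strategy_rows
            else pd.DataFrame()
        )
        return TruthJudgmentResults(self, effects, strategies, excluded)


class TruthJudgmentResults:
    """Fitted per-participant effects plus cohort-level tests."""

    def __init__(self, model, effects, strategies, excluded):
        self.model = model
        self.effects = effects
        self.strategies = strategies
        self.excluded = list(excluded)

    @property
    def n_included(self) -> int:
        return len(self.effects)

    @property
    def n_total(self) -> int:
        return len(self.effects) + len(self.excluded)

    def sign_counts(self, column: str) -> tuple[int, int, int]:
        """(positive, tied, negative) counts of a per-participant effect."""
        v = self.effects[column]
        return int((v > 0).sum()), int((v == 0).sum()), int((v < 0).sum())

    def nonparametric_tests(self) -> pd.DataFrame:
        """Two-condition Friedman tests and the interaction z.

        One row per contrast; counts are participants with a positive, tied,
        and negative effect.  The z row compares the proportion of
        participants rating near conjunctions truer than far against the
        proportion rating near disjunctions truer than far.
        """
        rows = []
        for name in ("distance_effect_conj", "distance_effect_disj", "minimum_effect", "maximum_effect"):
            pos, tied, neg = self.sign_counts(name)
            rows.append(
                {
                    "contrast": name,
                    "statistic": "friedman_chi2r",
                    "value": fstats.friedman_two_conditions(pos, tied, neg),
                    "n_positive": pos,
                    "n_tied": tied,
                    "n_negative": neg,
                    "N": self.n_included,
                }
            )
        conj_near_higher = int((self.effects["distance_effect_conj"] > 0).sum())
        disj_near_higher = int((self.effects["distance_effect_disj"] < 0).sum())
        try:
            z = fstats.two_proportion_z(conj_near_higher, disj_near_higher, self.n_included)
        except ZeroDivisionError:
            z = float("nan")
        rows.append(
            {
                "contrast": "interaction_proportions",
                "statistic": "two_proportion_z",
                "value": z,
                "n_positive": conj_near_higher,
                "n_tied": self.n_included - conj_near_higher - disj_near_higher,
                "n_negative": disj_near_higher,
                "N": self.n_included,
            }
        )
        return pd.DataFrame(rows)

    def paired_tests(self) -> pd.DataFrame:
        """Paired t, Cohen's d (= t/√N) and BIC Bayes-factor approximations.

        The interaction row tests the one-df repeated-measures contrast
        (near − far)_conj − (near − far)_disj.
        """
        e = self.effects
        contrasts = {
            "distance_effect_conj": e["distance_effect_conj"],
            "distance_effect_disj": -e["distance_effect_disj"],  # near − far, as rated
            "minimum_effect": e["minimum_effect"],
            "maximum_effect": -e["maximum_effect"],  # near disj − max, as rated
            "interaction": e["distance_effect_conj"] + e["distance_effect_disj"],
        }
        rows = []
        for name, diffs in contrasts.items():
            try:
                t, df, d = fstats.paired_t_and_d(diffs.to_numpy())
                bf = fstats.bic_bayes_factor(t, df + 1)
            except (ValueError, ZeroDivisionError):
                t = d = bf = float("nan")
                df = max(self.n_included - 1, 0)
            rows.append({"contrast": name, "t": t, "df": df, "cohens_d": d, "bf10_bic": bf})
        return pd.DataFrame(rows)

    def mean_table(self) -> pd.DataFrame:
        """Cohort means of the six rating summaries (Table-1-style)."""
        cols = [
            "near_conj_mean",
            "far_conj_mean",
            "near_disj_mean",
            "far_disj_mean",
            "min_constituent_mean",
            "max_constituent_mean",
        ]
        return self.effects[cols].mean().to_frame("mean").T

    def summary(self) -> str:
        buf = io.StringIO()
        print("Truth-judgment distance/minimax analysis", file=buf)
        print(f"  design: {self.model.design.variant}", file=buf)
        print(
            f"  participants: {self.n_total} total, {self.n_included} with equal pairs, "
            f"{len(self.excluded)} excluded",
            file=buf,
        )
        if len(self.strategies):
            n_avg = int((self.strategies["label"] == "Averaging").sum())
            print(
                f"  strategy: {n_avg} Averaging, {len(self.strategies) - n_avg} Logical",
                file=buf,
            )
        if self.n_included:
            print("\nMean ratings (near/far compounds and constituent bounds):", file=buf)
            print(self.mean_table().round(3).to_string(index=False), file=buf)
            print("\nNonparametric tests:", file=buf)
            print(self.nonparametric_tests().round(3).to_string(index=False), file=buf)
            if self.n_included >= 2:
                print("\nPaired contrasts:", file=buf)
                print(self.paired_tests().round(3).to_string(index=False), file=buf)
        return buf.getvalue()
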