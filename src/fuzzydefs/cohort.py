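"""Synthetic rating cohorts with the experiments' statistical structure.

Each simulated participant owns a generative distribution of interval
definitions and one of two judgment strategies:

* ``sampling`` ("logical") — every statement is judged by drawing a fresh
  sample of definitions and taking the containment proportion, with the
  participant's contraction–expansion adjustment applied to compounds;
* ``averaging`` — simple statements are judged as above, but a compound's
  truth is the mean of its constituents' freshly estimated simple truths.

A truth in [0, 1] becomes a 1–6 rating through the affine map
``round(1 + 5·truth + noise)`` clamped to the scale (half-up rounding);
the map is a design choice — any monotone map preserves the model's ordinal
predictions — and optional Gaussian noise emulates response variability.
Cohorts mix the two strategies, draw per-participant distribution parameters
from normal hyper-distributions (zero hyper-variance recovers identical
participants), and present the full stimulus design in a seeded shuffled
order with no immediate repeats.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .design import Sentence, StimulusDesign, build_design, shuffle_presentation
from .model import (
    ConnectiveAdjustment,
    DefinitionDistribution,
    NO_ADJUSTMENT,
    sample_definitions,
    truth_conjunction,
    truth_disjunction,
    truth_simple,
)

__all__ = ["ParticipantProfile", "CohortConfig", "judge", "sentence_truth", "generate_cohort"]

Strategy = Literal["sampling", "averaging"]


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: object
    dist: DefinitionDistribution
    strategy: Strategy = "sampling"
    n_definitions: int = 100
    adjustment: ConnectiveAdjustment = NO_ADJUSTMENT
    rating_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_definitions < 1:
            raise ValueError("n_definitions must be at least 1")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be non-negative")


def sentence_truth(profile: ParticipantProfile, sentence: Sentence, rng: np.random.Generator) -> float:
    """Truth in [0, 1] of one sentence under the participant's strategy.

    Every evaluation — including each constituent estimate of an averaging
    judge — draws its own fresh definition sample.
    """
    if sentence.kind == "simple":
        defs = sample_definitions(profile.dist, profile.n_definitions, rng)
        return truth_simple(defs, sentence.ages[0])
    if profile.strategy == "averaging":
        truths = [
            truth_simple(sample_definitions(profile.dist, profile.n_definitions, rng), a)
            for a in sentence.ages
        ]
        return float(np.mean(truths))
    defs = sample_definitions(profile.dist, profile.n_definitions, rng)
    if sentence.kind in ("conjunction2", "conjunction3"):
        return truth_conjunction(defs, sentence.ages, profile.adjustment)
    if sentence.kind == "disjunction":
        return truth_disjunction(defs, sentence.ages, profile.adjustment)
    raise ValueError(f"unknown sentence kind {sentence.kind!r}")


def truth_to_rating(truth: float, noise_sd: float, rng: np.random.Generator) -> int:
    raw = 1.0 + 5.0 * truth + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return int(min(6, max(1, math.floor(raw + 0.5))))


def judge(profile: ParticipantProfile, sentence: Sentence, rng: np.random.Generator) -> int:
    """Rate one sentence on the 1–6 scale."""
    return truth_to_rating(sentence_truth(profile, sentence, rng), profile.rating_noise_sd, rng)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative settings.

    Per-participant ``center_mean`` and ``width_mean`` are drawn from normal
    hyper-distributions (widths redrawn until positive); ``center_sd`` is
    shared and the width SD is a fixed proportion of the participant's mean
    width.  ``averaging_proportion`` of participants use the averaging
    strategy, the rest sample definitions.
    """

    n_participants: int = 31
    variant: str = "experiment-1"
    center_mean_mean: float = 45.0
    center_mean_sd: float = 3.0
    width_mean_mean: float = 15.0
    width_mean_sd: float = 3.0
    center_sd: float = 5.0
    width_sd_proportion: float = 0.5
    averaging_proportion: float = 0.0
    n_definitions: int = 100
    expansion_years: float = 0.0
    contraction_years: float = 0.0
    rating_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.averaging_proportion <= 1.0:
            raise ValueError("averaging_proportion must lie in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _draw_participants(config: CohortConfig, rng: np.random.Generator) -> list[ParticipantProfile]:
    n = config.n_participants
    n_avg = int(round(config.averaging_proportion * n))
    strategies = np.array(["averaging"] * n_avg + ["sampling"] * (n - n_avg))
    rng.shuffle(strategies)
    profiles = []
    for i in range(n):
        center_mean = rng.normal(config.center_mean_mean, config.center_mean_sd)
        width_mean = rng.normal(config.width_mean_mean, config.width_mean_sd)
        for _ in range(1000):
            if width_mean > 0:
                break
            width_mean = rng.normal(config.width_mean_mean, config.width_mean_sd)
        else:
            raise RuntimeError("could not draw a positive participant width_mean")
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i + 1:03d}",
                dist=DefinitionDistribution(
                    center_mean=center_mean,
                    center_sd=config.center_sd,
                    width_mean=width_mean,
                    width_sd=config.width_sd_proportion * width_mean,
                ),
                strategy=str(strategies[i]),
                n_definitions=config.n_definitions,
                adjustment=ConnectiveAdjustment(
                    expansion_years=config.expansion_years,
                    contraction_years=config.contraction_years,
                ),
                rating_noise_sd=config.rating_noise_sd,
            )
        )
    return profiles


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a complete, reproducible ratings table for a cohort.

    Each participant rates the full design — three presentations of every
    simple sentence, one of every compound — in a shuffled order with no
    immediate identical repeats.  The output uses the tidy ratings dialect
    consumed by :class:`~fuzzydefs.analysis.TruthJudgmentAnalysis`, with a
    ``strategy`` column recording the generating strategy for audit.
    """
    design = build_design(config.variant)
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants + 1)
    profiles = _draw_participants(config, np.random.default_rng(children[0]))
    trial_templates: list[Sentence] = []
    for s in design.sentences():
        reps = design.simple_repetitions if s.kind == "simple" else 1
        trial_templates.extend([s] * reps)

    rows = []
    for profile, seq in zip(profiles, children[1:]):
        rng = np.random.default_rng(seq)
        order = shuffle_presentation(trial_templates, rng)
        rep_counter: dict[Sentence, int] = {}
        for trial_index, sentence in enumerate(order, start=1):
            rep_counter[sentence] = rep_counter.get(sentence, 0) + 1
            ages = list(sentence.ages) + [None] * (3 - len(sentence.ages))
            rows.append(
                {
                    "participant_id": profile.participant_id,
                    "kind": sentence.kind,
                    "age1": ages[0],
                    "age2": ages[1],
                    "age3": ages[2],
                    "rating": judge(profile, sentence, rng),
                    "repetition": rep_counter[sentence],
                    "trial_index": trial_index,
                    "strategy": profile.strategy,
                }
            )
    df = pd.DataFrame(rows)
    df[["age2", "age3"]] = df[["age2", "age3"]].astype("Int64")
    return df
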