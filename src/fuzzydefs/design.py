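"""Stimulus designs for the middle-age truth-rating experiments.

The first experiment rates 13 simple ages (three repetitions each on a 1–6
scale) plus every pairwise conjunction and disjunction of the 11 ages between
25 and 65 inclusive, younger age first.  The second experiment adds, for each
double conjunction, a triple conjunction whose third age is the rounded
midpoint of the pair, and rewords conjunctions accordingly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import pandas as pd

__all__ = [
    "SIMPLE_AGES",
    "Sentence",
    "StimulusDesign",
    "build_design",
    "triple_middle",
    "render_sentence",
    "shuffle_presentation",
]

Variant = Literal["experiment-1", "experiment-2"]
Kind = Literal["simple", "conjunction2", "conjunction3", "disjunction"]

#: Ages used in the simple sentences, in presentation-sequence order.
SIMPLE_AGES: tuple[int, ...] = (15, 25, 30, 33, 37, 40, 45, 50, 53, 57, 60, 65, 75)

#: Compound sentences draw on the simple ages from 25 through 65 inclusive.
COMPOUND_AGE_RANGE: tuple[int, int] = (25, 65)


def triple_middle(younger: int, older: int) -> int:
    """Age halfway between the pair, rounded to the nearest whole age.

    Exact halves round up (40, 45 → 43).
    """
    if younger >= older:
        raise ValueError("younger must be strictly less than older")
    return (younger + older + 1) // 2


@dataclass(frozen=True)
class Sentence:
    """One sentence to rate: kind, its ages (ascending) and rendered text."""

    kind: Kind
    ages: tuple[int, ...]
    text: str

    ARITY = {"simple": 1, "conjunction2": 2, "conjunction3": 3, "disjunction": 2}

    def __post_init__(self) -> None:
        if len(self.ages) != self.ARITY[self.kind]:
            raise ValueError(f"{self.kind} takes {self.ARITY[self.kind]} ages, got {self.ages}")
        if tuple(sorted(self.ages)) != self.ages:
            raise ValueError("ages must be sorted ascending")


def render_sentence(kind: Kind, ages: tuple[int, ...], variant: Variant = "experiment-1") -> str:
    """Render the exact sentence frame used in the experiments."""
    if len(ages) != Sentence.ARITY[kind]:
        raise ValueError(f"{kind} takes {Sentence.ARITY[kind]} ages, got {ages}")
    if kind == "simple":
        return f"A person is middle-aged at {ages[0]}."
    if kind == "disjunction":
        return f"A person is middle-aged at either {ages[0]} or {ages[1]} or both."
    if kind == "conjunction2":
        if variant == "experiment-1":
            return f"A person is middle-aged at both {ages[0]} and {ages[1]}."
        return f"A person is middle-aged at both of these ages: {ages[0]} and {ages[1]}."
    if kind == "conjunction3":
        if variant != "experiment-2":
            raise ValueError("triple conjunctions exist only in the experiment-2 design")
        return (
            "A person is middle-aged at all three of these ages: "
            f"{ages[0]}, {ages[1]}, and {ages[2]}."
        )
    raise ValueError(f"unknown sentence kind {kind!r}")


@dataclass(frozen=True)
class StimulusDesign:
    variant: Variant
    simple_ages: tuple[int, ...]
    compound_ages: tuple[int, ...]
    conjunction_pairs: tuple[tuple[int, int], ...]
    disjunction_pairs: tuple[tuple[int, int], ...]
    triples: tuple[tuple[int, int, int], ...]
    simple_repetitions: int = 3

    def sentences(self) -> list[Sentence]:
        """Every distinct sentence of the design (repetitions not expanded)."""
        out = [
            Sentence("simple", (a,), render_sentence("simple", (a,), self.variant))
            for a in self.simple_ages
        ]
        out += [
            Sentence("conjunction2", p, render_sentence("conjunction2", p, self.variant))
            for p in self.conjunction_pairs
        ]
        out += [
            Sentence("disjunction", p, render_sentence("disjunction", p, self.variant))
            for p in self.disjunction_pairs
        ]
        out += [
            Sentence("conjunction3", t, render_sentence("conjunction3", t, self.variant))
            for t in self.triples
        ]
        return out

    def n_trials(self) -> int:
        """Number of rated trials per participant, repetitions included."""
        return (
            len(self.simple_ages) * self.simple_repetitions
            + len(self.conjunction_pairs)
            + len(self.disjunction_pairs)
            + len(self.triples)
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per sentence (kind, age1..age3, text), for audit export."""
        rows = []
        for s in self.sentences():
            ages = list(s.ages) + [None] * (3 - len(s.ages))
            rows.append(
                {"kind": s.kind, "age1": ages[0], "age2": ages[1], "age3": ages[2], "text": s.text}
            )
        return pd.DataFrame(rows)


def build_design(variant: Variant = "experiment-1") -> StimulusDesign:
    """Construct the full stimulus design for either experiment."""
    if variant not in ("experiment-1", "experiment-2"):
        raise ValueError(f"unknown design variant {variant!r}")
    lo, hi = COMPOUND_AGE_RANGE
    compound = tuple(a for a in SIMPLE_AGES if lo <= a <= hi)
    pairs = tuple(itertools.combinations(compound, 2))  # younger first
    triples: tuple[tuple[int, int, int], ...] = ()
    if variant == "experiment-2":
        triples = tuple((x, triple_middle(x, y), y) for x, y in pairs)
    return StimulusDesign(
        variant=variant,
        simple_ages=SIMPLE_AGES,
        compound_ages=compound,
        conjunction_pairs=pairs,
        disjunction_pairs=pairs,
        triples=triples,
    )


def shuffle_presentation(sentences: list, rng, max_tries: int = 1000) -> list:
    """Seeded shuffle of a trial list with no immediate identical repeats.

    ``sentences`` may contain duplicates (the three repetitions of each simple
    sentence); a shuffle is repaired by swapping an offending trial with a
    later compatible position, retrying from scratch if repair fails.
    """
    trials = list(sentences)
    for _ in range(max_tries):
        seq = [trials[i] for i in rng.permutation(len(trials))]
        ok = True
        for i in range(1, len(seq)):
            if seq[i] != seq[i - 1]:
                continue
            for j in range(i + 1, len(seq)):
                fits_here = seq[j] != seq[i - 1]
                # the displaced trial must not create a duplicate around j
                fits_there = (seq[i] != seq[j - 1] or j - 1 == i) and (
                    j + 1 >= len(seq) or seq[i] != seq[j + 1]
                )
                if fits_here and fits_there:
                    seq[i], seq[j] = seq[j], seq[i]
                    break
            else:
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError("could not arrange trials without immediate repeats")
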