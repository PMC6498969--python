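"""Factorial simulation of the contraction–expansion model.

Each grid cell fixes the definition-generating distribution (central age
Normal(45, center_sd); width Normal(width_mean, proportion·width_mean)
truncated at zero) and a single expansion–contraction factor applied per end
(expansion for conjunctions, contraction for disjunctions).  For every
simulated participant each simple age is evaluated three times (averaged,
mirroring the experiments' three presentations) and every compound once,
every evaluation with its own fresh sample of definitions.  The resulting
truth proportions are then pushed through the same equal-pair / near-far
analysis used for human ratings, and effects are reported in percentage
points of the [0, 1] truth scale.

Equal pairs are, by default, found exactly the way the experiments find
them: each simple evaluation is expressed on the 1–6 rating scale through
the affine map round(1 + 5·truth), the three ratings are averaged, and two
ages tie when their mean ratings are exactly equal (ties at the scale floor
excluded as vacuous).  Finding ties on the raw truth proportions instead
demands exact equality of Monte-Carlo counts, which concentrates the
admitted pairs at near-zero truths and shrinks every effect; the rating
grid is both the coarseness at which the experiments themselves operate
and the default here.  A truth-scale tolerance mode is available as a
sensitivity control.

The default grid is the full 3 × 5 × 3 × 4 = 180-cell factorial:
center SD ∈ {2, 5, 8}, mean width ∈ {10, 12, 15, 18, 20}, width-SD
proportion ∈ {0.2, 0.5, 1.0}, expansion–contraction ∈ {0, 1, 2, 3} years,
with 100 definitions per evaluation and 100 participants per cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import TruthProfile, build_near_far, find_equal_pairs, find_peak, participant_effects
from .design import StimulusDesign, build_design
from .model import MAX_WIDTH_RESAMPLES

__all__ = ["SimulationConfig", "run_condition", "run_grid", "GRID_COLUMNS"]


@dataclass(frozen=True)
class SimulationConfig:
    center_mean: float = 45.0
    center_sd_grid: tuple[float, ...] = (2.0, 5.0, 8.0)
    width_mean_grid: tuple[float, ...] = (10.0, 12.0, 15.0, 18.0, 20.0)
    width_sd_proportion_grid: tuple[float, ...] = (0.2, 0.5, 1.0)
    ec_factor_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    n_definitions: int = 100
    n_participants: int = 100
    n_simple_repetitions: int = 3
    #: find equal pairs on the 1–6 rating grid (the experiments' own scale);
    #: False switches to ties on the raw truth proportions
    tie_on_ratings: bool = True
    #: truth-scale tie tolerance, used only when tie_on_ratings is False
    equal_pair_tol: float = 0.0
    variant: str = "experiment-1"
    seed: int = 0

    def cells(self) -> list[tuple[float, float, float, float]]:
        """(center_sd, width_mean, width_sd_proportion, ec_factor) tuples."""
        return list(
            itertools.product(
                self.center_sd_grid,
                self.width_mean_grid,
                self.width_sd_proportion_grid,
                self.ec_factor_grid,
            )
        )


GRID_COLUMNS = [
    "center_mean",
    "center_sd",
    "width_mean",
    "width_sd_proportion",
    "ec_factor",
    "n_definitions",
    "n_participants",
    "n_included",
    "near_conj_mean",
    "far_conj_mean",
    "near_disj_mean",
    "far_disj_mean",
    "min_constituent_mean",
    "max_constituent_mean",
    "distance_effect_conj_pct",
    "distance_effect_disj_pct",
    "minimum_effect_pct",
    "maximum_effect_pct",
    "far_minimum_effect_pct",
    "far_maximum_effect_pct",
]


def _sample_bounds(rng, shape, cm, cs, wm, ws):
    """Sampled definition bounds; widths rejected until non-negative."""
    c = rng.normal(cm, cs, size=shape)
    w = rng.normal(wm, ws, size=shape)
    if ws > 0:
        for _ in range(MAX_WIDTH_RESAMPLES):
            bad = w < 0
            n_bad = int(bad.sum())
            if n_bad == 0:
                break
            w[bad] = rng.normal(wm, ws, size=n_bad)
        else:
            raise RuntimeError("width resampling did not terminate")
    return c - w / 2.0, c + w / 2.0


def run_condition(
    center_sd: float,
    width_mean: float,
    width_sd_proportion: float,
    ec_factor: float,
    rng: np.random.Generator,
    *,
    config: SimulationConfig = SimulationConfig(),
    design: StimulusDesign | None = None,
) -> dict:
    """Simulate one grid cell and summarise it through the analysis pipeline.

    Returns a flat record (see ``GRID_COLUMNS``); a cell in which no
    participant yields an equal pair is flagged by ``n_included == 0`` with
    NaN effects rather than an exception.
    """
    design = design or build_design(config.variant)
    cm = config.center_mean
    ws = width_sd_proportion * width_mean
    n_def, n_part, n_rep = config.n_definitions, config.n_participants, config.n_simple_repetitions

    ages = np.asarray(design.simple_ages, dtype=float)
    pairs = np.asarray(design.conjunction_pairs, dtype=float)  # (n_pairs, 2) younger first

    # Simple statements: three independent evaluations per age, averaged.
    lo, hi = _sample_bounds(rng, (n_part, ages.size, n_rep, n_def), cm, center_sd, width_mean, ws)
    a = ages[None, :, None, None]
    rep_counts = ((lo <= a) & (a <= hi)).sum(axis=3)  # (part, age, rep) out of n_def
    simple_counts = rep_counts.sum(axis=2)  # out of n_rep * n_def
    # each evaluation on the experiments' 1–6 scale (half-up rounding), averaged
    rating_means = np.floor(1.0 + 5.0 * (rep_counts / n_def) + 0.5).clip(1, 6).mean(axis=2)

    # Conjunctions: expanded definitions must span both ages.
    lo, hi = _sample_bounds(rng, (n_part, len(pairs), n_def), cm, center_sd, width_mean, ws)
    amin = pairs[None, :, 0, None]
    amax = pairs[None, :, 1, None]
    conj_counts = ((lo - ec_factor <= amin) & (amax <= hi + ec_factor)).sum(axis=2)

    # Disjunctions: contracted definitions must contain at least one age.
    lo, hi = _sample_bounds(rng, (n_part, len(pairs), n_def), cm, center_sd, width_mean, ws)
    lo2, hi2 = lo + ec_factor, hi - ec_factor
    hit = ((lo2 <= amin) & (amin <= hi2)) | ((lo2 <= amax) & (amax <= hi2))
    disj_counts = hit.sum(axis=2)

    pair_keys = [tuple(int(v) for v in p) for p in design.conjunction_pairs]
    denom_simple = float(n_rep * n_def)
    per_participant = []
    for p in range(n_part):
        mean_by_age = {
            int(age): simple_counts[p, i] / denom_simple for i, age in enumerate(design.simple_ages)
        }
        if config.tie_on_ratings:
            tie_by_age = {int(age): rating_means[p, i] for i, age in enumerate(design.simple_ages)}
            tie_profile = TruthProfile(p, tie_by_age, find_peak(tie_by_age))
            eq = find_equal_pairs(tie_profile, floor=1.0)
        else:
            tie_profile = TruthProfile(p, mean_by_age, find_peak(mean_by_age))
            eq = find_equal_pairs(tie_profile, tol=config.equal_pair_tol, floor=0.0)
        if not eq:
            continue
        # effects are measured on the truth scale; the peak comes from the tie profile
        profile = TruthProfile(p, mean_by_age, tie_profile.peak)
        conj_vals = {k: conj_counts[p, j] / n_def for j, k in enumerate(pair_keys)}
        disj_vals = {k: disj_counts[p, j] / n_def for j, k in enumerate(pair_keys)}
        sets = [build_near_far(pair, tie_profile.peak, design) for pair in eq]
        eff = participant_effects(profile, conj_vals, disj_vals, sets)
        if eff is not None:
            per_participant.append(eff)

    row = {
        "center_mean": cm,
        "center_sd": center_sd,
        "width_mean": width_mean,
        "width_sd_proportion": width_sd_proportion,
        "ec_factor": ec_factor,
        "n_definitions": n_def,
        "n_participants": n_part,
        "n_included": len(per_participant),
    }
    if not per_participant:
        for col in GRID_COLUMNS[8:]:
            row[col] = float("nan")
        return row
    mean_of = lambda attr: float(np.mean([getattr(e, attr) for e in per_participant]))
    row.update(
        near_conj_mean=mean_of("near_conj_mean"),
        far_conj_mean=mean_of("far_conj_mean"),
        near_disj_mean=mean_of("near_disj_mean"),
        far_disj_mean=mean_of("far_disj_mean"),
        min_constituent_mean=mean_of("min_constituent_mean"),
        max_constituent_mean=mean_of("max_constituent_mean"),
        distance_effect_conj_pct=100.0 * mean_of("distance_effect_conj"),
        distance_effect_disj_pct=100.0 * mean_of("distance_effect_disj"),
        minimum_effect_pct=100.0 * mean_of("minimum_effect"),
        maximum_effect_pct=100.0 * mean_of("maximum_effect"),
        far_minimum_effect_pct=100.0 * mean_of("far_minimum_effect"),
        far_maximum_effect_pct=100.0 * mean_of("far_maximum_effect"),
    )
    return row


def run_grid(config: SimulationConfig = SimulationConfig(), progress=None) -> pd.DataFrame:
    """Run every cell of the factorial grid; one summary row per cell.

    Deterministic for a given config: each cell gets an independent child
    stream of the master seed, so subsetting the grid axes changes which
    cells run but a full-default run is reproducible bit-for-bit.
    """
    design = build_design(config.variant)
    cells = config.cells()
    seeds = np.random.SeedSequence(config.seed).spawn(len(cells))
    rows = []
    for (cell, seq) in zip(cells, seeds):
        rng = np.random.default_rng(seq)
        row = run_condition(*cell, rng, config=config, design=design)
        rows.append(row)
        if progress is not None:
            progress(row)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)
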