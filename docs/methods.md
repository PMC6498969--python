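# Methods

## The model

`fuzzydefs` implements a sampling account of graded category membership for
concepts definable as a range on one dimension, with *middle-age* as the
working example. The concept is represented not by a membership function but
by a population of crisp **definitions**, each a closed age interval
[c − w/2, c + w/2]. Generatively, centers are drawn c ~ Normal(μ_c, σ_c) and
widths w ~ Normal(μ_w, σ_w) with negative widths rejected and redrawn, so the
realised width distribution is a normal truncated at zero (rejection is
capped at 1000 vectorised passes and raises if exceeded; for any μ_w > 0 at
least half the mass is non-negative, so the cap is unreachable in valid
configurations).

Truth judgments are containment proportions over a fresh sample of
definitions (one sample per statement, never reused):

* simple, t(X): the proportion of sampled definitions containing X
  (containment closed on both ends; an empty interval contains nothing);
* conjunction, t(X ∧ Y ∧ …): the proportion containing *every* listed age —
  because definitions are contiguous this reduces to containing the youngest
  and oldest, which yields the triple identity t(A ∧ B ∧ C) = t(A ∧ C) for
  A < B < C on a shared sample;
* disjunction, t(X ∨ Y): the proportion containing *at least one* age.

The **contraction–expansion extension** widens each sampled definition by a
fixed number of years per end before a conjunction is evaluated and shrinks
it per end before a disjunction (39–51 with factor 1 becomes 38–52 for
conjunctions and 40–50 for disjunctions). Contraction may consume an
interval entirely; the resulting empty interval satisfies no statement —
the only consistent reading of per-end contraction. With both factors zero
the pure model is recovered, for which two bounds hold exactly on any
shared sample: t(X ∧ Y) ≤ min[t(X), t(Y)] and t(X ∨ Y) ≥ max[t(X), t(Y)].

Three truth-functional competitors are provided for contrast (product,
min/max, averaging), as is a **point-definition variant** in which each
sampled definition is a single age and a statement's score is 1/(1 + D),
where D is the mean (simple), mean-of-means (conjunction) or mean-of-minima
(disjunction) distance of the statement's ages to the sampled points. The
1/(1 + D) transform is a design choice: "inversely proportional"
underdetermines the map, any strictly decreasing transform preserves the
ordinal predictions, and those are all that is ever used (the variant
produces a distance effect for disjunctions but not conjunctions).

`expected_truth` is the analytic oracle: for each statement type the
center-condition is an interval (or union of intervals) given the width, so
the satisfaction probability is a normal CDF expression integrated over the
truncated-normal width density (`scipy.integrate.quad`, with integrand
breakpoints at the widths where the center-set changes topology). Degenerate
σ = 0 cases are evaluated in closed form. Monte-Carlo estimates at 10⁵
samples agree with the oracle within three binomial standard errors.

## Experimental designs

Both experiments rate 13 simple ages (15 … 75, three repetitions each, 1–6
scale) and all 55 pairwise conjunctions and disjunctions of the 11 ages
between 25 and 65, younger age first. The second experiment adds 55 triple
conjunctions whose middle age is the midpoint of the pair rounded to the
nearest whole age — exact halves round *up* (40, 45 → 43); "nearest" is
ambiguous at .5 and one rule had to be fixed — plus reworded conjunction
frames. Presentation order is a seeded shuffle with immediate repeats
repaired by swapping; order has no effect on any analysis and exists for
realism of generated datasets.

## The analysis pipeline

Per participant: repetition means give a truth profile; the peak is the age
(or plateau) with the maximal mean. **Equal pairs** are ages X below and Y
above the peak with exactly equal means — exact equality is safe in floating
point because all means share a denominator (k/3 for ratings,
k/(3·n_definitions) for simulated truths). Each member of an equal pair is
paired with its immediate neighbours in the age sequence (neighbours must
occur in compounds and not be a peak age), producing **near** pairs (A, X)
and corresponding **far** pairs (A, Y) whose constituent truths are
identical by construction. Effects, pooled over all of a participant's
admissible pairs:

* conjunction distance effect = mean near-conjunction − mean far-conjunction;
* disjunction distance effect = mean far-disjunction − mean near-disjunction;
* minimum effect = mean near-conjunction − mean smaller constituent;
* maximum effect = mean larger constituent − mean near-disjunction.

Participants with no admissible equal pair are excluded — a normal outcome,
not an error. **Ties at the scale floor are excluded by default** (rating
1.0, or truth 0): when two ages tie because no sampled definition contains
either, every compound built from them is equally false, so the near/far
comparison is vacuous; such ties only dilute effect estimates toward zero.
`floor=None` restores the strict include-everything behaviour, and a
truth-scale tolerance is available as a sensitivity control for noisy
proportions.

Strategy classification (second design): qualifying triples A < B < C have
the middle age strictly truer than both outer ages; triples whose middle age
was never rated as a simple sentence (midpoints such as 28) cannot qualify
since t(B) is undefined. A strict excess of the mean triple rating over the
corresponding outer-double mean assigns **Averaging**, anything else
**Logical**; zero qualifying triples yields Logical with the count flagged.
Interval sampling predicts equality of the two means, so sampling judges
fall on either side by noise alone and their classification is near chance —
only averaging-judge recovery is a stable property.

Cohort statistics: the two-condition Friedman χ²r is computed from
positive/tied/negative sign counts with ties mid-ranked and no
tie-correction denominator — this convention reproduces the published
statistic for this design exactly. The interaction of question type with
pair distance is tested nonparametrically by a pooled two-proportion z and
parametrically by the one-df paired contrast
(near − far)_conj − (near − far)_disj, whose squared t equals the
repeated-measures interaction F. Cohen's d is mean/SD of the difference
scores (= t/√N). Bayes factors use the unit-information BIC approximation
BF₁₀ = exp(ΔBIC/2) with R² = t²/(t² + n − 1); this tracks order of
magnitude only and published unit-information values computed by other
software will not be matched exactly — they are documented as approximate,
never calibrated against.

## Synthetic cohorts

`generate_cohort` produces complete, reproducible rating tables. Each
participant owns a definition distribution and a strategy: **sampling**
judges evaluate every statement by containment proportion over a fresh
sample (adjustment applied to compounds); **averaging** judges estimate each
constituent's simple truth by fresh sampling and average them. Truth maps to
the 1–6 scale by round(1 + 5·truth) (half-up) plus optional Gaussian noise,
clamped — the experiments specify no mapping, and an affine map preserves
every ordinal prediction while keeping summary tables on a comparable scale.

Defaults, chosen once for realism: per-participant center mean ~ N(45, 3)
years and width mean ~ N(15, 3) years (truncated positive) give
between-participant variation in peaks and equal-pair structure; shared
center SD 5 (the intermediate published grid value); width SD half the width
mean; 100 definitions per judgment; averaging mixture 0.4 (the observed
classified fraction is ≈ 17/44); rating noise SD 0.5 for realistic datasets
and 0 for recovery checks. Zero hyper-variance recovers the
identical-participant mode. What the generator does not emulate: response
times, order or anchoring effects, scale-use idiosyncrasies, or within-
participant reuse of a definition sample across related statements — so
passing recovery tests show that the pipeline detects the intended
structure, not that human data contain it.

## The simulation grid

The factorial grid crosses center SD {2, 5, 8} × mean width
{10, 12, 15, 18, 20} × width-SD proportion {0.2, 0.5, 1.0} ×
expansion–contraction factor {0, 1, 2, 3} years (180 cells), with 100
definitions per evaluation and 100 participants per cell; each simple age is
evaluated three times (averaged), mirroring the three experimental
presentations. Effects are reported in percentage points of the truth scale
(100 × differences of mean truths). Each cell draws an independent child
stream of the master seed, so runs are bit-for-bit reproducible.

Equal pairs inside the simulation are found, by default, exactly the way the
experiments find them: each simple evaluation is expressed on the 1–6 scale
through the same affine map, the three ratings are averaged, and ties are
exact on that grid (floor ties excluded). Demanding exact equality of the
raw Monte-Carlo proportions instead admits ties almost only where counts
have the least variance — near truth zero — and systematically shrinks every
effect; the rating grid is the coarseness at which the experiments
themselves operate. This choice is the main reproduction risk for the
simulation summaries and is exposed (`tie_on_ratings`, `--tie-scale`)
together with a truth-scale tolerance mode for sensitivity analysis.

Known limitation: with the per-end expansion defined above, the
near-conjunction minimum effect for an informative equal pair is
approximately the expansion factor times the normal density at the binding
interval boundary, which for factors of 2–3 years reaches 10–25 percentage
points in the steeper cells (closed-form example: μ_c = 45, σ_c = 2, w = 10,
tie (40, 50), near pair (37, 40), expansion 2 gives
P(33 ≤ c ≤ 44) − P(32 ≤ c ≤ 42) ≈ 0.31 − 0.07 = 24 pts). Published
characterisations of the minimum effect as staying within single digits at
small expansion factors are not reproducible under this operationalisation;
the package reports what the model as specified produces.

## Problem sizes and numerics

Default problem sizes (100 participants × 100 definitions × full designs)
run a 15-cell grid slice in ~1.3 s and the full 180-cell grid in ~25 s on
one core, with containment fully vectorised over (participant, statement,
definition) arrays. Acceptance recomputation runs 105 cells in ~10 s.
Tie-breaking and degenerate inputs: plateau peaks span lowest-to-highest
maximal age; zero-variance difference scores raise rather than return
infinities; a grid cell with no includable participant is flagged
(`n_included = 0`, NaN effects) rather than raising; truths are exact 0/1 in
fully degenerate cells and match the oracle.
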