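# Methods

## The composite score

The package implements a weighted composite injury-risk score over four
dimensionless biomechanical ratios:

| component | meaning | weight | normal range | risk threshold |
|---|---|---|---|---|
| FV | coefficient of variation of peak vertical GRF across gait cycles | 0.35 | 0.08–0.15 | > 0.18 |
| TA | stance-time difference ratio between limbs | 0.28 | 0.05–0.12 | > 0.15 |
| LD | spatial pressure-distribution index | 0.22 | 0.10–0.18 | > 0.22 |
| BA | kinematic/kinetic limb-comparison index | 0.15 | 0.06–0.14 | > 0.18 |

The score is

    WASe = (w1·FV + w2·TA + w3·LD + w4·BA) · Ω,

clipped to [0, 1].  Weights come from a two-step derivation: the midpoint of
each component's literature-reported contribution range (FV 30–40%,
TA 25–30%, LD 20–25%, BA 10–20%) is normalised to unit sum and rounded to
two decimals with round-half-to-even — the only standard rounding rule that
reproduces the published coefficients (0.275 → 0.28, 0.225 → 0.22) exactly.
If rounding breaks the unit sum, the largest weight absorbs a single ±0.01
correction; anything beyond that is an error.

Ω is a critical-transitions early-warning factor,
Ω = Σᵢ(wᵢ·Vᵢ·σᵢ²)/(√T·ΔH), combining the weighted product of each
component's current value Vᵢ and its variance σᵢ² over an observation
window of length T (sessions) with an entropy shift ΔH.  Rising component
variance — the classic precursor of a critical transition — inflates Ω and
hence the score.  Three deliberate choices:

* **Vᵢ is the raw current component value.**  Nothing in the formulation
  requires a transformed value, so none is applied.
* **ΔH and T are inputs, not estimates.**  The package provides no entropy
  estimator; dynamic use supplies both scalars from whatever monitoring
  pipeline produced them.  ΔH within 1e−6 of zero makes Ω undefined
  (division blow-up) and raises.
* **Negative Ω clamps to 0 with a warning.**  ΔH < 0 (entropy decreasing,
  the system moving *away* from a transition) would otherwise produce a
  negative risk score; the score is documented as bounded in [0, 1], and the
  clamp plus warning keeps that contract explicit rather than silent.
  Clipping of the final score likewise records a `clipped` flag, because the
  [0, 1] bound is not algebraically guaranteed once Ω ≠ 1.

The cohort study runs entirely in **cross-sectional mode with Ω = 1**: each
virtual athlete contributes one component vector, so σᵢ², T and ΔH have no
cohort analogue.  `compute_omega` exists for windowed (dynamic) use only.
Whether Ω should be normalised so the population-mean score is scale-stable
is left open; with Ω fixed at 1 the question does not arise in the study.

Component risk flags use strict inequalities (a value exactly at the
threshold is not flagged), matching the published "greater-than" thresholds.

## The virtual cohort

`generate_cohort` emulates a 1,000-athlete population:

* **Demographics.**  Sex (50/50) and sport (40% running / 30% jumping /
  30% cutting) use *exact* stratified counts via largest-remainder
  apportionment, shuffled into random order.  Exact counts were chosen over
  binomial/multinomial draws because the reference population table reports
  exactly 500/500 and 400/300/300.  Age is normal(24.5, 5.2) truncated to
  [18, 35] — the truncation bounds make the two age bands (18–25, 26–35)
  partition the cohort; note the realised mean/SD of a truncated normal
  differ from the untruncated parameters (≈25.3 ± 4.0 here).  Training
  hours are normal(8.5, 3.1) truncated at zero.
* **Components.**  True values are drawn from a 4-variate normal with means
  (0.15, 0.08, 0.12, 0.10), SDs (0.04, 0.03, 0.05, 0.04), and a correlation
  matrix whose off-diagonals (0.45, 0.35, 0.55, 0.25, 0.65, 0.30) span the
  empirically reported 0.25–0.65 band; positive definiteness is asserted at
  load time.  The joint 4-vector is rejection-sampled into the observed
  component ranges (FV 0.08–0.25, TA 0.05–0.20, LD 0.10–0.28, BA 0.06–0.22):
  rejection preserves the joint shape where clipping would pile mass at the
  bounds.  A consequence worth knowing: joint truncation shifts the
  marginals beyond what one-dimensional truncation predicts (the FV mean
  lands near 0.164, not 0.153), because the asymmetric truncation of
  correlated components drags its neighbours.  Tests verify the marginals
  against one-dimensional quadrature in the independence case and against an
  independent quasi-Monte-Carlo box-mean oracle in the correlated default.
* **Measurement noise.**  Each measured component is the true value times
  (1 + N(0, 0.05)) — a 5% coefficient of variation is naturally
  multiplicative for positive ratios — re-drawn per element until it
  respects the same bounds.
* **Randomness.**  One master seed (default 42) spawns named substreams
  (demographics, components, noise, outcomes) via `SeedSequence.spawn`, so
  adding a stage never perturbs earlier draws and every pipeline product is
  a pure function of (config, seed).

## Injury linkage and calibration

Outcomes follow a logistic model on the standardised score:
p = expit(β₀ + β₁·(s − s̄)/sd), one independent Bernoulli draw per athlete.
The linkage uses the *measured* (noisy) score — the feature set an observer
actually has — with a documented switch to true-component scoring for
sensitivity experiments.

`calibrate_linkage` fixes (β₀, β₁) by nested root-finding: the outer search
(Brent, β₁ ∈ [0, 50]) targets an **expected AUC** of 0.89 and the inner
search targets a mean injury probability of 0.20.  The expected AUC is
computed without resampling by treating each athlete as a case with weight
pᵢ and a control with weight 1 − pᵢ and accumulating
P(case score > control score) + ½·P(tie) in one rank-sum pass; it is
provably non-decreasing in β₁ (tested on a grid) and equals 0.5 at β₁ = 0,
so the bracket is monotone.  The nominal intercept bracket [−20, 20] widens
geometrically when a steep slope pushes the root outside it.  Both residuals
are verified below 1e−4; the calibration is a fixed point of itself.  On the
default cohort the solution is β₀ ≈ −2.30, β₁ ≈ 2.11.

## Evaluation battery

All diagnostics are authored in-package (scikit-learn serves only as an
independent cross-check in tests):

* **ROC/AUC** by Mann–Whitney rank sum with midrank tie handling, verified
  equal to brute-force pair counting on all small instances.  Positive
  classification is strictly `score > threshold` throughout.
* **Operating point** by Youden-J maximisation over all cut points, ties
  broken toward higher sensitivity, then lower threshold.  Inside
  cross-validation the threshold is re-derived on training folds only.
* **Bootstrap CIs**: stratified (cases and controls resampled separately,
  preserving prevalence), percentile method, B = 2000, with capped redraws
  of resamples on which a statistic is undefined.
* **DeLong comparison**, unpaired two-sample variant (subgroups are
  disjoint), with AUC variances from the placement-value estimator
  S₁₀/m + S₀₁/n.
* **Hosmer–Lemeshow** with g = 10 equal-count bins (largest-remainder
  sizing, tied probabilities kept together, zero-expectation bins merged
  into a neighbour), χ² over events and non-events, df = bins − 2.
* **Cross-validation**: stratified 5-fold by outcome with seeded shuffling.
* **Subgroups** (sex, age band, sport) evaluated at the *global* Youden
  threshold — mirroring one deployed framework across groups — with
  pairwise DeLong tests; the three-sport family is summarised by the
  max-AUC vs min-AUC pair alongside all three pairwise results.
* **Weight sensitivity** holds the cohort and outcomes fixed and re-scores
  under each ±0.05 single-weight perturbation (renormalised) plus 100
  random weight vectors drawn uniformly in the ±0.05 box around the
  defaults and renormalised.  Because outcomes were linked to the
  default-weight score, perturbations can essentially only lower AUC.
  Outcomes are simulated exactly once per replicate; no analysis re-draws
  them.

## What the study reproduces — and what it cannot

With the calibration targets above, the 20-replicate default study yields
(replicate means): prevalence 20.0%, full-cohort AUC 0.892, CV mean AUC
0.892 with fold-SD ≈ 0.02, Youden sensitivity 0.839, and max |ΔAUC| ≈ 0.002
under single-weight perturbations — comfortably inside the published < 0.03
stability bound.

The published operating-point triple (sensitivity 0.82, specificity 0.87,
accuracy 0.85) is **not jointly reproducible**: it implies Youden
J = 0.69, while the maximum J attainable on a near-binormal ROC with
AUC 0.89 is ≈ 0.63 (a J of 0.69 would require AUC ≈ 0.93).  Under the
calibrated conditions the Youden point lands at J ≈ 0.631 ± 0.030, with
sensitivity and specificity individually wandering (SD ≈ 0.05) along the
nearly flat Youden ridge — observed means ≈ 0.84 / 0.79, accuracy ≈ 0.80.
The acceptance checks assert the published values anyway and fail honestly
on specificity and accuracy.  Relatedly, the published PPV/NPV (0.79/0.89)
are inconsistent with prevalence 0.20 via Bayes' rule; the package reports
the Bayes-consistent values (PPV ≈ 0.51–0.53, NPV ≈ 0.95 at the realised
operating point).

## What the simulator does not emulate

Sport- and sex-specific component shifts (a config hook exists but defaults
to zero — subgroup differences are pure sampling noise by construction),
longitudinal within-athlete dynamics (hence Ω = 1), injury-severity grades,
non-Gaussian measurement error, and any feedback from intervention.
Passing tests therefore demonstrate internal mathematical consistency of
the scoring-and-evaluation machinery under idealised conditions, not
real-world predictive performance.

## Problem sizes and numerics

Default study sizes: n = 1000 athletes, 20 replicate seeds, B = 2000
bootstrap resamples (primary replicate), 5 CV folds, 10 calibration bins,
8 + 100 weight configurations — the full battery runs in seconds.
Root-finding tolerance 1e−6 (residuals checked at 1e−4); rejection sampling
capped at 500 rounds with a clear infeasibility error; weight arithmetic in
decimal to make the half-even rounding exact; floats serialised at 17
significant digits so CSV/JSON round-trips are lossless.
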