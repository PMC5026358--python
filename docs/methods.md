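# Methods

## The measurement problem

Non-symbolic dot comparison is the standard paradigm for assessing the
acuity of the approximate number system (ANS): on each trial two dot sets
are shown and the participant picks the more numerous one. Many indices
have been computed from such data — mean accuracy, probit-regression Weber
fractions, distance and ratio effects on accuracy or response time,
inverse efficiency, composites — and they are frequently treated as
interchangeable. This package implements the full stack of these
estimators, their reliability and association analyses, the simulation
machinery showing how estimator choice shapes the acuity–effect
relationship, and a generator producing synthetic experiments with known
ground truth, so every stage can be validated end to end.

## Accuracy models and Weber-fraction estimation

Three parameterizations link a single width parameter w (the Weber
fraction; smaller w = sharper numerosity representations) to choice
probabilities:

- **Linear (scalar-variability) model.** Tuning curves on a linear scale
  with width proportional to numerosity give
  `p_correct(r, w) = Φ(|r − 1| / (w √(r² + 1)))`, with r the numerosity
  ratio in either convention (the predictor is invariant under r ↔ 1/r).
- **Log-Gaussian model.** Fixed-width tuning on a log scale gives
  `p_choose_right(r_num, w) = ½ + ½ erf(log2(r_num) / (2w))`, equivalently
  `p_correct = Φ(|log2 r_num| / (√2 w))`, with `r_num = n_right / n_left`.
- **Modified log (DeWind) model.** Adds an intercept (side bias) and two
  visual predictors: `p_choose_right = Φ(β_side + β_num log2 r_num +
  β_size log2 r_size + β_spacing log2 r_spacing)`, where `log2 r_size` is
  the sum of item-surface-area and total-surface-area log-ratios and
  `log2 r_spacing` the sum of field-area and sparsity log-ratios.

Each reduces to a binomial GLM with probit link. The linear and log
models are no-intercept fits of *correctness* on one transformed
predictor, with `w = 1/β` (linear) and `w = 1/(√2 β)` (log); the modified
model is an intercepted fit of the *chosen side* on signed predictors,
with `w = 1/(√2 β_num)`. The GLM engine is statsmodels' IRLS; the wrapper
adds convergence and separation flags (|linear predictor| > 30 is treated
as separation) so that degenerate data never yields a silently finite
slope.

**Exclusion rule.** A participant's Weber estimate is excluded when the
slope is not significantly different from zero (two-sided Wald test,
α = .05), the fit did not converge, or the slope is non-positive; w > 2
is additionally flagged. A Wald rather than likelihood-ratio test is used
because the rule is phrased in terms of the fitted coefficient; the
p-value is exposed so users can apply a different rule. For true chance
responders this excludes ≈ 95 % of cases (the 50 % with a negative
fitted slope plus the non-significant positive half).

## Per-participant measures

Eleven indices per participant × condition: mean accuracy (all ratios
pooled); NDE_acc and NRE_acc (intercepted probit-GLM slopes of
correctness on distance D = |n₁ − n₂| and ratio R = min/max); the three
Weber fractions; mean RT (all responses by default — correct-only is an
option; the two are nearly collinear in practice); NDE_RT and NRE_RT (OLS
slopes of RT on D and R, ms per unit predictor); inverse efficiency
(mean correct-response RT / proportion correct, ms); and a z-composite
(average of the across-cohort z-scores of mean accuracy and mean RT, no
sign flip, so it correlates positively with both inputs).

Slopes are per unit predictor internally; a `per0.1` reporting option
rescales ratio slopes to a 0.1-ratio increment, the scale on which
percent-correct ratio effects of a few percent are naturally read. A
separate linear-model ratio effect on percent correct
(`ratio_effect_linear_percent`) serves as the manipulation-check variant
used when comparing conditions; it is deliberately distinct from the
probit NRE_acc.

RT trimming removes trials beyond k = 3 SD of the participant ×
condition mean in a single pass (mean and SD computed once, both tails,
sample SD). Zero-SD groups are untouched. On default synthetic cohorts
the loss is below 2 % of trials.

## Reliability

Split-half reliability: per replicate, each participant's trials are
randomly split into two equal halves (odd trial assigned by a seeded
draw), the measure computed per half, halves correlated across
participants (Pearson — the standard input to the prophecy formula), and
corrected to full length by Spearman–Brown `2r/(1+r)`. One hundred
replicates are averaged by default; correction is applied per replicate
before averaging (the average-then-correct alternative is a switch, as is
a ratio-stratified split). Participants on whom a measure is undefined
for a half are dropped pairwise from that replicate, and the dropped
fraction is logged.

## Association and multiplicity

Measure tables are correlated with Spearman's rho (ties averaged,
t-approximation p-values), pairwise-complete so that Weber-excluded
participants are dropped per pair rather than listwise. The
Benjamini–Hochberg step-up adjustment is applied over the lower triangle
of one condition's table — one family per table, mirroring per-table
significance marks. BH is monotone and dominates the raw p-values but is
not idempotent on arbitrary re-application; the tests assert the
properties that actually hold (dominance, bounds, order preservation).

## Explained variance and condition effects

Per participant and condition, `r2_ols` is the coefficient of
determination of RT on ratio, and `r2_lr` the likelihood-ratio
(Cox–Snell) pseudo-R² of a logit GLM of correctness on ratio,
`1 − exp((2/n)(ℓ₀ − ℓ₁))`; Nagelkerke rescaling is available as a switch
but off by default since the two are not compared across scales here.
Condition effects on these per-participant indices are tested with a
one-way repeated-measures ANOVA implemented in closed form (F on
(k−1, (k−1)(n−1)) df; Greenhouse–Geisser epsilon from the double-centered
within-participant covariance matrix, clipped to [1/(k−1), 1]), verified
against pingouin in the test suite. Omnibus trial-level ANOVAs with
ratio as a continuous covariate are deliberately replaced by this
per-participant-effect + repeated-measures route: the interaction
questions of interest ("does the ratio effect differ across conditions?")
are exactly questions about the per-participant effects, and the route
avoids a heavy trial-level mixed model. Planned contrasts are paired
t-tests with BH adjustment.

## The estimator-shape simulation

For each Weber fraction on a grid (default 0.10–0.90 in steps of 0.01,
100 simulated participants per value), per-ratio correct counts are drawn
from Binomial(80, p) with p from the linear model at the five design
ratios, and the accuracy ratio effect is estimated three ways: OLS slope
of proportion correct on ratio; the categorical contrast
`(acc_large − acc_small)/acc_large` with small = {0.5, 0.6} and large =
{0.8, 0.9} (a symmetric split around the excluded middle ratio; the split
is configurable); and the probit-GLM slope. The headline property — both
linear-model estimators are curvilinear in w (a given effect size is
ambiguous between sharp and poor acuity) while the probit estimator is
monotone — is checked by `shape_diagnostics`: curves of per-w means are
smoothed with a centered 5-point moving average, and excursions smaller
than twice the median per-w standard error count as noise. A curve is
monotone when it never moves against one direction by more than that
tolerance, and has an interior extremum when the smoothed extremum sits
strictly inside the grid with both endpoints clearing it by more than the
tolerance. The smoothing window and the factor 2 are repo constants
chosen once for a qualitative shape call at cohort sizes of a few dozen
per grid point; the acceptance run uses a 17-point grid × 40 participants,
which reproduces the same shape calls as denser grids.

## The synthetic-data generator

The generator emulates a multi-condition dot-comparison experiment:

- **Item sets** restrict to integer pairs whose exact min/max ratio
  equals the nominal design ratio (e.g. ratio 0.9 in [10, 40] admits
  exactly (18, 20), (27, 30), (36, 40)), sampled uniformly with
  replacement, 80 per ratio by default, with the larger side
  counterbalanced left/right. The original stimulus inventories of
  published experiments are not printed in text, so exact-ratio sampling
  is the reproducible stand-in.
- **Visual features** are drawn per item: four component log-ratios with
  half-normal magnitudes (SD 0.3 each) summed into `log2 r_size` and
  `log2 r_spacing`, with a congruency-mix parameter controlling how often
  the visual cues favor the more numerous side (0.5 = uncorrelated).
  Pixel-level rendering is out of scope; only the feature summaries the
  modified log model consumes are generated.
- **Choice and RT** come from a drift-diffusion responder: evidence
  starts at a/2 between absorbing bounds 0 and a, drifts at
  `v = sign(log2 r_num) · v_scale · |log2 r_num| / w` with unit diffusion
  noise, Euler–Maruyama steps of 1 ms with a Brownian-bridge correction
  for within-step boundary crossings (without which the discrete walk
  overshoots the bounds and inflates accuracy); upper bound = "choose
  right"; RT = first-passage time + non-decision time t0. Conditions
  scale the threshold (and may shift t0), moving the speed–accuracy
  criterion without touching w. The drift–w link is a modeling choice of
  this generator: it makes ratio effects, Weber recovery and the
  trade-off all emerge from one mechanism, but it is not itself estimated
  from data.
- **Accuracy-only sampling** draws Bernoulli responses directly from any
  of the three accuracy models, for estimator tests without RT machinery.

Defaults (chosen once to emulate an adult cohort): w ~ truncated
N(0.6, 0.3²) on [0.1, 2], matching reported adult linear-model Weber
fractions (mean ≈ 0.6, SD ≈ 0.35); threshold a = 1, drift scale 1,
t0 = 0.25 s, which puts the default cohort near 70 % mean accuracy and
≈ 480 ms mean RT; instruction-style condition multipliers
{accuracy: 1.5, combined: 1.0, speed: 0.7}; a per-condition time-base tag
records whether RT is measured from stimulus offset (restricted
presentation) or onset (self-paced).

**What the generator does and does not emulate.** With heterogeneous
thresholds and common w it produces the positive accuracy–RT coupling of
a speed–accuracy trade-off; with heterogeneous w and a common threshold,
the negative coupling expected if both measures indexed acuity. Because
absorption probability in a diffusion process depends on the product
v·a, a criterion shift moves accuracy too: accuracy-derived Weber
estimates scale approximately as 1/a, so they are criterion-*dependent*
under this generator — exact threshold-invariance of recovered w is not
attainable in any pure diffusion responder, and tests assert the
direction of the dependence rather than invariance. The responder also
omits non-decision-time variability and inter-trial drift variability,
so its RT carries a cleaner ratio signal than human RT: the
explained-variance asymmetry (ratio explains more of accuracy than of
RT) comes out direction-correct but less extreme than in real data.
Passing tests therefore validate the estimators and the mechanism, not
the magnitudes of human effect sizes.

## Numerical choices

- IRLS: statsmodels defaults, max 100 iterations, tolerance 1e−8;
  separation flagged at |linear predictor| > 30.
- Nominal ratios are interpreted as rationals
  (`Fraction(r).limit_denominator(1000)`) so exact-ratio item
  enumeration is immune to float representation of e.g. 0.7.
- Sample SD (ddof = 1) throughout trimming and z-scoring.
- All randomness flows from a single master seed through
  `numpy.random.SeedSequence` spawns, one stream per pipeline stage, so
  toggling a stage does not shift another stage's draws and fixed seeds
  give byte-identical outputs.
- Problem sizes for the validation runs: Weber recovery uses 200
  replicates per (model, w) at the standard 400-trial design; the
  estimator-shape run uses a 17-point w grid × 40 participants; the
  trade-off cohorts use 60 participants × 200 trials. These sizes give
  stable qualitative calls and tight medians while keeping a full
  validation run around half a minute; the full 81 × 100 grid is
  available through `ansacuity simulate-fig11`.

## Known limitations

- XLSX import is a convenience reader requiring an explicit column map;
  the canonical interchange format is the trial CSV.
- The modified log model is fitted only when visual log-ratios are
  present for all trials of a participant.
- No lapse-rate or guessing parameters, no Bayesian fitting, no diffusion
  *fitting* (generation only), and no trial-level mixed models.
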