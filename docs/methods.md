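# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the limitations of `koalasdm`.

## The observation problem

Citizen-collected occurrence data are doubly non-random: the *detection*
process concentrates where people are (near roads and paths), and the
*reporting* process favors sightings over non-sightings. A naive logistic
regression on such data confounds habitat quality with accessibility and
prevalence. The pipeline applies three corrections jointly:

1. **Pseudo-absences with weights.** True absences are too few to anchor
   the background. Ten background cells per presence cell are drawn
   uniformly without replacement from cells with no reports, each given
   response 0 and weight 0.1, so the background carries the same total
   weight as the presences. Observed cells keep weight = report count
   (≥1). Because any single background draw is arbitrary, the entire
   fit-and-rank procedure is repeated over independent draws
   (`n_iterations`, default 100; seeds are `base_seed + i` so any subset
   is reproducible) and rankings are aggregated by the median.
2. **An effort offset.** Each cell contributes 1/max(d, d_min) to the
   linear predictor with fixed coefficient 1, where d is the distance in
   metres from the cell centroid to the nearest road and d_min = 1 m
   floors on-road cells. A configurable multiplier `offset_scale`
   (default 1) allows probing stronger effort corrections.
3. **A spatial block random intercept.** Cells inherit a shared intercept
   per 2×2-cell block (4 km²), absorbing residual spatial autocorrelation
   that fixed effects cannot explain. (Block side length is
   configurable.)

## Model and estimation

Weighted binomial GLM/GLMM with logit link. Prior weights multiply the
per-row Bernoulli log-likelihood terms; for binary data the saturated
log-likelihood is zero, so deviance = −2·loglik. The GLM is fitted by
IRLS (coefficient tolerance 1e-8, ≤100 iterations). Non-convergence,
degenerate responses, and |β|>50 are flagged as possible separation on
the result, never silently ignored; rank-deficient designs raise with the
offending column names.

The GLMM marginal likelihood integrates the block intercepts out with a
**Laplace approximation**. Blocks are conditionally independent, so the
integral factorizes into one-dimensional block integrals evaluated at the
joint penalized mode:

    ℓ(β, σ) = Σ_i w_i ℓ_i(β, û) − Σ_b û_b²/(2σ²) − ½ Σ_b log(1 + σ² W_b)

where W_b is the block's summed IRLS weight at the mode. The inner
problem (joint mode over β and u) is a penalized IRLS solved through the
Schur complement of the diagonal random-effect block — O(n·p²) per
iteration regardless of the number of blocks. The outer problem is a
bounded scalar search over log σ (tolerance 1e-6, σ ∈ [1e-6, 10]); at the
lower bound the model collapses exactly to the GLM and σ²_α is reported
as 0. Standard errors come from the Schur-complement information matrix;
`k` counts fixed effects plus the variance component. Laplace was chosen
as the standard default of mixed-model tooling in this field; the test
suite validates it against adaptive 21-node Gauss–Hermite quadrature
(agreement ~1e-3 on large-block data) and the implementation was checked
against `lme4::glmer` (coefficients, SEs, σ and logLik agree to 4
decimals on a reference fit).

Sample size for AICc/BIC is the design row count (observed +
pseudo-absence rows), not the weight sum: the fractional weights are bias
corrections, not replicate counts. Per iteration, models are ranked by
AICc; wAICc/wBIC use the max-shifted softmax so no exponential overflows.
Cohen's κ dichotomizes fitted probabilities at 0.5 (configurable) on the
weighted confusion table. Cross-validation stratifies folds by response
and scores the weighted mean absolute error between held-out responses
and predicted probabilities (conditional modes applied when the held-out
block was seen in training). Nakagawa–Schielzeth R² uses the variance of
the fixed-effect linear predictor (offset excluded) and the logit
distribution-specific variance π²/3, reported ×100. Moran's I
correlograms use binary axis-aligned ("rook-ring") neighbor classes at
cell offsets (±d, 0)/(0, ±d), the normal approximation under the
randomization null, and a Bonferroni-corrected per-lag level α/n_lags.
The rook-ring definition was chosen so the 2×2 checkerboard attains the
theoretical minimum I = −1 at lag 1. Non-converged fits are excluded from
their iteration's ranking with a logged warning rather than failing the
run.

Model-averaged effect sizes standardize each coefficient by its standard
error, weight it by the model's share of wAICc *among models containing
that predictor* (fractions sum to 1 per predictor), sum within an
iteration, and average across iterations.

## Suitability and abundance

Suitability maps use population-level prediction: no random effect (block
levels are undefined off the training area) and the training-mean offset
as a common reference effort, with training centering constants
reapplied; per-iteration predictions are averaged cell-wise for the
top-ranked model only. Density scales linearly as D(s) = s·D_max/2,
reaching half the maximum published density at perfect suitability; cell
densities sum to the population. D_max is the mean of published
upper-level density estimates after excluding extreme values >4 ha⁻¹
(mean 1.57, SD 1.19 ha⁻¹ for the bundled table — a synthetic stand-in
matching the published summary, to be replaced by real values for a real
analysis). The interval is mean × (1 ± SD/D_max): symmetric about the
mean with relative half-width equal to the coefficient of variation of
the density estimates, floored at zero. A literal ±2·SD construction
would produce a negative lower density bound; the relative-CV form is the
construction consistent with the published bounds and is what the package
implements.

## The synthetic data generator

The generator emulates the features of the survey that matter
statistically, not any real geography:

- **Predictor fields** are moving-average-filtered white noise (3-cell
  kernel), mutually independent except rain, which is a monotone function
  of elevation plus smooth noise whose amplitude is calibrated by
  bisection (≤50 iterations) until the realized Spearman ρ is within
  ±0.005 of the 0.90 target. Vegetation areas share each cell through a
  softmax allocation so classes never exceed the cell area. Scales are
  chosen to be field-plausible (elevation ~300±150 m, temperature range
  ~12±1.5 °C, road densities log-normal around 0.7–1.5 km per km²).
- **Roads** form a minimum-spanning-tree network over random waypoints —
  sparse, connected, and irregular.
- **Occupancy** is drawn from the same model family the pipeline fits
  (logistic in centered predictors, block random intercept), with default
  coefficients making temperature range the dominant negative driver and
  intercept −2.5 (≈20–25% occupancy).
- **Reports** sample cells with probability ∝ exp(−d/decay), decay 0.5 km
  by default; road bias in opportunistic surveys is well documented but
  has no canonical functional form, so the exponential decay and its
  scale are calibration choices. At the
  default 1,359 reports with 8.5% absences on a 75×75 grid this yields
  ≈250 presence and ≈30 absence cells — the imbalance regime of the
  motivating survey. Absences cluster on a limited set of search sites
  (~3.5 reports per site). Coordinates are jittered within the cell and
  rounded to 0.01 landscape units to emulate coarse web-reported fixes.

What passing tests on this generator do **not** show: robustness to real
vegetation maps and climatologies (the fields here are smooth and
stationary), to geodesic distortion (coordinates are abstract Cartesian
km), to misidentified species, or to detection probability varying with
vegetation density. The generator's bias is purely distance-to-road.

## Problem sizes

The default pipeline configuration mirrors the survey scale (75×75 grid,
100 iterations, 10-fold CV). The test suite and the acceptance script use
reduced sizes chosen to keep the statistical properties detectable:
20 iterations for ranking recovery, 20 replicates for variance-recovery
and autocorrelation-reduction rates, 30–50 cell grids for property tests.
For the autocorrelation-reduction property the generating random field
uses 4×4-cell blocks (matched in the fitted GLMM): residual
autocorrelation in real surveys extends beyond a single 2×2 block, and at
2×2 both models' residual I values are so close to zero that the
comparison is dominated by the GLMM's small negative shrinkage
autocorrelation (≈ −1/(block size−1) within blocks).

## Known limitations

- One random-effect level only (no crossed/nested effects, no CAR or
  Matérn spatially correlated fields); logit link only.
- The rain/elevation exclusion is hard-coded in the candidate set; the
  collinearity screen itself is advisory.
- Coefficient uncertainty is not propagated into the abundance interval;
  the interval reflects only the spread of the maximum-density estimates.
- The suitability→density rule is the linear-to-half-D_max form; no
  saturating alternatives.
- Mixed presence/absence cells resolve to presence; surveys with
  informative absences at presence locations would need a different rule.
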