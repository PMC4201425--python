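# koalasdm

Bias-corrected species distribution modelling and abundance estimation for
presence-biased citizen-science surveys, built around the koala
(*Phascolarctos cinereus*) occurrence-modelling problem in South Australia.

Opportunistic wildlife surveys produce data with three systematic defects:
observers report sightings far more often than non-sightings (prevalence
bias), they search near roads and paths (effort bias), and neighboring grid
cells are not independent (spatial autocorrelation). `koalasdm` implements
a complete, reusable pipeline that confronts all three and then converts
the fitted habitat-suitability surface into a population estimate. Because
raw survey data of this kind are rarely deposited, the package ships a
first-class synthetic-data generator that reproduces the statistical
structure of such a survey — road-clustered reports, extreme
presence/absence imbalance, a strongly correlated rain/elevation predictor
pair — so the entire workflow is testable end to end.

## The model

Occurrence on a 1-km² grid is modelled as a weighted binomial GLMM with
logit link:

    logit P(y_i = 1) = x_i'β + offset_i + u_{b(i)},   u_b ~ N(0, σ²_α)

- **Response & weights** — a cell with any sighting is a presence; its
  weight is its report count. Ten pseudo-absence cells per presence are
  drawn uniformly from the background and down-weighted to 0.1, and the
  draw is repeated (100 iterations by default) so the ranking is not an
  artefact of one background sample.
- **Effort offset** — 1/distance (m) from cell centroid to the nearest
  road enters the linear predictor with a fixed coefficient, standing in
  for sampling effort.
- **Spatial random intercept** — one `u_b` per 2×2-cell (4 km²) block
  absorbs residual spatial autocorrelation; the marginal likelihood is
  computed by a Laplace approximation (validated against adaptive
  Gauss–Hermite quadrature and `lme4`).
- **Model selection** — a fixed 15-candidate set over predictor groups
  (vegetation classes, water, temperature range, elevation, rain, roads;
  rain and elevation never together, their Spearman ρ ≈ 0.9), ranked by
  AICc with evidence weights, %deviance explained, Cohen's κ, k-fold CV
  error, Moran's I residual correlograms, and Nakagawa–Schielzeth R²m/R²c.
- **Abundance** — suitability *s* maps linearly to density *s·D*max/2,
  where *D*max is the mean of published maximum densities (values
  >4 ha⁻¹ excluded); summing cells gives the population, with an interval
  of relative half-width SD/*D*max.

## Worked example

```
python examples/04_abundance.py
```

prints

```
density table: 10 values, 1 excluded (> 4.0/ha)
D_max = 1.57 +/- 1.19 per ha = 157 +/- 119 per km^2 (CV 75.6%)

study area 5576 km^2, suitability sum 1448
population estimate: 113,630 (interval 27,670 - 199,589)
implied mean density: 5.0 - 35.8 per km^2
```

The first two lines summarize the maximum-density table (the bundled file
is a synthetic stand-in whose post-exclusion mean and SD sit at the
published operating point). A suitability surface averaging ≈0.26 over a
5,576-km² frame then scales to ≈114,000 animals; the wide interval is the
coefficient of variation of the published density estimates, and dividing
the bounds by the area gives the implied mean-density range of 5.0–35.8
animals per km².

The other examples walk through each stage: `01_synthetic_survey.py`
(road-biased report generation), `02_grid_and_design.py` (gridding,
offsets, pseudo-absences, the collinearity screen), `03_fit_and_rank.py`
(the 15-model GLMM ranking and model-averaged effect sizes — with data
generated from the full environmental+roads structure, that model wins
with wAICc ≈ 0.92 and temperature range is the dominant, negative
effect), and `05_full_pipeline.py` (the one-call `run_pipeline` with a
byte-reproducible output bundle).

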