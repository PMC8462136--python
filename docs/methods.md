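# Methods

This note documents the models and procedures the package implements,
the synthetic landscape generator's assumptions, the numerical choices,
and what the package's tests do and do not establish about real survey
data.

## The modelling problem

Lake-level survey data for an invasive macrophyte come in three forms:
presence–absence (surveyed lakes only, true absences known),
presence-only (presences plus unsurveyed lakes treated as
pseudoabsences), and abundance (frequency of occurrence: the share of
within-lake point-intercept sample points with a detection, in [0, 1]).
The package fits a random forest to each response type — a
classification forest for occurrence (suitability = fraction of trees
voting presence), a regression forest for abundance — over 11 lake-level
environmental covariates, optionally augmented by a spatial
autocovariate, and then evaluates discrimination and functional accuracy
separately. The point of the design is that these two notions of
accuracy can rank models in opposite order.

## Response datasets and pseudoabsence strategies

From one lake table, five datasets are assembled (complete-case rule:
any lake missing a covariate is dropped, with a logged count):

- **PA** — all surveyed lakes, binary label.
- **PO_random / PO_distant / PO_proximal** — all presences plus
  `n_pseudo` pseudoabsences (default: the number of true absences, so
  class balance matches PA) drawn uniformly without replacement from
  unsurveyed lakes: from the whole pool, from outside the convex hull of
  presence coordinates, or from inside it. Surveyed true absences are
  excluded (replaced, not augmented). Lakes on the hull boundary count
  as inside (proximal); a deterministic tie-break on a measure-zero set.
  A shortfall in a strategy's candidate cell is an explicit error; lakes
  are never silently topped up from the other cell.
- **ABUNDANCE** — all surveyed lakes, frequency-of-occurrence label.

A single global hull is used; no multi-part or per-presence recomputed
hulls.

## Spatial statistics

- **Weights**: distance-band neighborhoods with inverse-distance weights
  w_ij = 1/d_ij, row-standardized. The band radius defaults to "auto" —
  the maximum nearest-neighbor distance, the smallest radius leaving no
  isolated point. Duplicate coordinates are rejected (1/d undefined)
  with a hint to jitter.
- **Autocovariate**: ac_i = Σ_j w_ij y_j / Σ_j w_ij, the weighted mean
  of neighboring responses. It is computed once on the full dataset
  before any train/test split, as spatial-lag SDMs commonly do; the
  information leak this implies is deliberate, reproduced as part of the
  procedure under study, and logged at attach time. For predicting onto
  lakes outside a model's dataset (functional accuracy), the
  autocovariate is computed from the model's own dataset responses, with
  zero-distance sources excluded and a nearest-source fallback for
  targets with an empty band.
- **Moran's I** uses the row-standardized weights and a one-sided
  permutation test, p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm), with 999
  permutations by default; permutation rather than the normal
  approximation for small-sample robustness.
- **Pair correlation g(r)**: ring-count estimator against the expected
  pair count under complete spatial randomness at the window intensity,
  with no edge correction. It is used only to pick a block scale;
  boundary bias at the relevant radii (≤ ~30 km in a 600 × 560 km
  window) is a few percent and does not move the clustering-scale
  argument.
- **Spatial blocks**: square-grid tessellation; blocks are dealt to k
  folds (default 5) in random order, each to the currently smallest
  fold, so fold sizes differ by at most the largest block occupancy and
  all lakes of a block share a fold. Block side defaults to 10 km
  (5 km for the proximal dataset, whose pseudoabsences are spatially
  restricted).

## Evaluation

- **AUC** is the rank-based (Mann–Whitney) statistic with midrank tie
  correction. **TSS** and **Kappa** need a threshold: the
  sensitivity–specificity equality rule evaluates candidate cutoffs
  (midpoints of consecutive unique scores plus guards) and picks the one
  minimizing |sens − spec|, ties broken by larger sens + spec, then by
  the lower cutoff. The threshold is always fit on the training fold's
  predictions and applied to the held-out fold — stated for blocked CV,
  and applied to all schemes for consistency and to avoid leakage.
- **Schemes**: nonindependent = stratified 5-fold CV repeated (50
  iterations by default), metrics averaged over all fold-level values
  (a simple mean; equivalent to averaging iterations up to fold-count
  weighting); quasi-independent = one stratified 70/30 split; spatially
  blocked = block folds, single-class folds skipped with a warning, the
  scheme failing if at least half are skipped. The combined average is
  the arithmetic mean of the three schemes' values.
- **Functional accuracy** correlates predictions of the *final
  full-data* model with frequency of occurrence over all surveyed lakes
  (r_all, ρ_all) and over invaded lakes only (r_nonzero, ρ_nonzero,
  undefined below 3 lakes). Zero-abundance lakes tend to inflate the
  correlation — both variants are always reported.
- **Wedge**: linear quantile regression (check-loss minimization via the
  standard iterative reweighting in statsmodels) of frequency of
  occurrence on suitability at τ = 0.50, 0.75, 0.90; wedge strength =
  slope(0.90) − slope(0.50).
- **Importance**: percent increase in held-out MSE when one predictor
  column is permuted (Brier-style MSE of predicted suitability against
  the 0/1 label for occurrence models), averaged over repeats. Held-out
  permutation rather than out-of-bag keeps the measure learner-agnostic;
  out-of-bag importances from a bagged implementation would differ in
  detail but not in ranking behavior.
- **Forests**: 500 trees, √p features per split (classification), p/3
  (regression), unlimited depth; all exposed. The 70/30 split is
  stratified by class for occurrence models to stabilize threshold
  estimation.

## The synthetic landscape

The generator emulates the structure of a regional invasion survey, not
any particular lake. Defaults are the study design: 184 surveyed
presences, 284 surveyed absences, 801 unsurveyed lakes on a 600 × 560 km
extent (roughly the latitudinal and longitudinal span of Minnesota's
lake region).

- **Lake positions**: a Thomas cluster process (60 parents, 10 km
  dispersion — the scale at which the real lakes stop clustering), so
  spatial blocking and g(r) are meaningful. Uniform placement is
  available (`cluster_scale=None`).
- **Covariates**: 11 fields with the published marginal moments
  (mean/SD/min/max) of the real lake predictors. Each field is a
  distance-decay kernel mixture of white noise at random nodes (range
  80 km) plus a 20% white-noise nugget, rescaled to the target moments
  and clipped to the published range. Heavy-tailed variables
  (chlorophyll-a, lake size, phosphorus: SD ≥ mean) get a lognormal
  marginal instead, so the published minima/maxima are respected without
  mass clipping. Water-temperature degree days carry a dominant
  north–south linear gradient (variance share 0.95; kernel remainder at
  150 km range) — the regional climatic structure that confines the
  invaded range to the warm part of the landscape, as in the real
  system. Without that gradient the presence hull sprawls over most of
  the extent and the distant/proximal pseudoabsence cells become
  infeasible for a 284-lake draw.
- **Suitability**: s_i = logistic(β₀ + Σ_c β_c · ramp_c(x_ic) + λ·L_i),
  where each ramp rises linearly from the covariate's observed landscape
  minimum to its plateau and is flat beyond it. Plateaus default to the
  response shapes reported for the real system: degree days ≈ 1,750
  °C·days, lake depth ≈ 30 m, road density ≈ 75 m/ha. Weights default to
  24 (degree days) and 4 (depth, road density): the climatic driver
  dominates, and the sharp logistic keeps suitability near zero in the
  cold region so the presence hull stays compact. L is a latent
  spatially structured field (range 40 km, weight 1) standing for
  unmeasured drivers (dispersal, connectivity); it creates the residual
  spatial autocorrelation that motivates the autocovariate. β₀ is
  calibrated by bisection so the landscape-mean suitability equals a
  target prevalence (0.36), which makes the fixed presence/absence
  counts feasible; presence is drawn Bernoulli(s_i) and redrawn up to a
  budget (100) until the counts can be met, then surveyed lakes are
  sampled from the successes/failures. By default survey status is
  independent of suitability; a `survey_bias` knob (> 0 skews surveyed
  lakes toward high suitability) exists but is off, since the original
  survey's site-selection process is unknown.
- **Abundance**: for presences, true within-lake cover is
  0.8 · s_i · u_i with u_i ~ Beta(1.2, 3) (right-skewed, mean ≈ 0.29):
  suitability caps attainable cover without determining it, which is
  exactly what produces the wedge. The 0.8 cap matches the largest
  frequency of occurrence seen in the field data. Observed frequency is
  Binomial(100, cover)/100 — a 100-point point-intercept survey. A
  presence whose draw is 0 is redrawn once and floored at 1/100, so
  presence always implies a nonzero frequency.
- **Preset variants**: `three_driver_config` (latent effect off,
  homogeneous 80 km ranges, weights 8/5/5) gives a landscape where
  *exactly* three covariates generate suitability — the clean fixture
  for driver-recovery checks; the degree-day weight is raised relative
  to depth/road because most lakes sit above its plateau, shrinking its
  effective variation. `strong_residual_config` (latent weight 3)
  produces occurrence data with strong spatial structure no covariate
  explains — the regime where the autocovariate becomes the leading
  predictor.

**What the generator does not emulate**: real lake geometry and shoreline
shape, survey-year dynamics, observer error in the point-intercept
method, covariate measurement error, spatial sampling bias in which
lakes get surveyed, and correlations *between* covariates (fields are
generated independently; real limnological variables co-vary). Passing
tests therefore show that the pipeline's statistical machinery behaves
correctly and that the discrimination/functional contrast emerges under
a plausible invasion geometry — not that the effect sizes match any
particular real dataset.

## Problem sizes used by the tests and the acceptance script

Replicated experiments (20 seeded landscapes) run the nonindependent
scheme at 3 CV iterations instead of 50 and forests at 300 trees instead
of 500; medians over seeds are insensitive to both choices, and the
landscape design itself (lake counts, covariate structure, suitability
model) is never scaled. The Moran permutation-test calibration check
uses 500 replicates of 200 points with 499 permutations; the test's size
property does not depend on the point count.

## Known limitations

- Pseudoabsence strategies beyond the three hull-based ones
  (environmental stratification, target-group background, buffers) are
  out of scope.
- The pair correlation estimator has no edge correction; g(r) is biased
  low near the window boundary.
- Quantile regression fits are unpenalized straight lines; crossing
  quantile curves are possible in principle on small samples.
- The autocovariate's neighborhood definition (distance band, auto
  radius, row standardization) is one reasonable choice among several
  used in the spatial-lag SDM literature; the radius is configurable.
- Functional accuracy uses full-data predictions (the conventional
  abundance–suitability protocol); a held-out variant can be obtained by
  passing a split model, but is not the reported default.
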