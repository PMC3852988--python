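# Methods

This note documents the models and procedures implemented in `sharksdm`,
the defaults and numerical choices, what the synthetic scenarios do and do
not emulate, and the known limitations.

## The estimation problem

Basking-shark surface sightings are presence-only records collected under
uneven effort. The pipeline estimates a monthly habitat-suitability surface
over a raster study area from (a) presence points and (b) ten co-registered
environmental predictors per month: depth, slope, aspect, distance to the
0/50/100/150/200 m isobaths, chlorophyll-a and sea-surface temperature.

Surface sightings are treated as proxies for habitat use at depth. The
supporting check is geometric: the horizontal displacement of a dive phase
is `|vertical rate| × duration × tan(90° − |pitch|)`. For the mean descent
(0.22 m s⁻¹, 189 s, 20.54°) this is ≈111 m, for the mean ascent (0.22 m s⁻¹,
208 s, 9.78°) ≈265 m — both far below the 2.5 km cell size, so a shark seen
at the surface is almost surely sighted in the cell of the habitat it is
using.

## Raster model

A `Grid` is a 2-D array (row 0 = north), a missing-data mask, a lower-left
origin in projected meters and a square cell size (2 500 m ⇒ 6.25 km²
cells). Monthly predictors form an `EnvStack` under an **intersection
mask**: a cell masked in any layer (land, the near-shore exclusion ring,
undefined aspect) is excluded everywhere, so all statistics see one common
cell set.

Numerical choices, stated so tests can be exact:

* **Gradient** — central differences over the 4-neighborhood; slope
  `arctan |∇z|` in degrees, aspect the compass direction of increasing depth
  (steepest descent of the seafloor), clockwise from north. Cells without a
  complete unmasked 4-neighborhood are masked; zero-gradient cells have
  slope 0 and masked aspect.
* **Contours** — a contour cell either equals the level exactly or is one of
  a 4-neighbor pair lying strictly on opposite sides of it (both cells of
  the pair are marked, keeping the definition symmetric). Distances are
  center-to-center Euclidean, 0 on contour cells, computed with a k-d tree
  and verified against an exhaustive O(cells²) oracle.
* **Resampling** — nearest-neighbor by output-cell-center lookup, the method
  used for harmonizing mixed-resolution predictors; masks propagate.
* **Climatology means** — cellwise over months, a cell masked only where all
  inputs are masked (partial cloud cover keeps the remaining months).

## Spatial thinning

Clustered effort (whale-watch trips near port) violates the independence of
presences. The thinning routine computes the average-nearest-neighbor
statistic — observed mean NN distance over `0.5/√(n/A)`, its expectation
under complete spatial randomness — and then greedily decimates points in a
seeded random order, keeping a point iff it is at least the expected NN
spacing from every kept point. The classical (uncorrected) statistic is
used, with the supplied study area when given and the bounding-rectangle
area otherwise. Months whose thinned set would hold ≤ 5 points are left
unthinned (`skipped=True`): tiny samples carry little redundancy. By
default unique sighting locations are thinned rather than expanded
individuals (`thin_expanded` switches this). Moran's I correlograms
(binary in-bin weights; null expectation −1/(n−1)) and semivariograms are
provided as diagnostics only — no variogram model is fitted.

## Maximum-entropy model

The suitability model is the Gibbs density over background cells

    p_λ(i) = exp(Σ_j λ_j f_j(i)) / Z(λ),

the maximum-entropy distribution subject to presence feature-mean
constraints. Features are the standard suite built from each predictor
after min–max scaling to [0,1] over the background: linear, quadratic,
pairwise products, threshold steps `1[x > knot]` and hinges
`max(0, x − knot)/(max − knot)`, with up to 10 knots per variable at evenly
spaced interior quantiles (a desk-scale default; constant variables are
skipped with a warning). Background cells are all valid cells up to a cap
of 10 000 (uniform seeded sample beyond that), with presence cells always
included among the background — the standard convention.

Fitting maximizes the penalized mean presence log-probability

    (1/m) Σ_presence log p_λ(i)  −  β Σ_j s_j |λ_j|,
    s_j = SD_background(f_j) / √m,

by proximal-gradient (ISTA) ascent with backtracking line search:
deterministic, tolerance 1e-5 on the max weight update, 500 iterations by
default, exact zeros via soft-thresholding so the AICc parameter count
`k = #{λ_j ≠ 0}` is well defined. The per-feature scale `s_j` is a single
simplified rule rather than per-class tables; it preserves the property
that weakly varying features are penalized less in absolute terms.
Training gain is the mean presence log-probability relative to uniform,
in nats. The cumulative output rescales raw probabilities to 0–100:
`cum(i) = 100·Σ_{raw(j) ≤ raw(i)} raw(j)`, ties sharing a value and the
best cell(s) scoring exactly 100. No logistic output and no clamping or
projection outside the background range are provided.

## Regularization selection and evaluation

For each month one model per candidate β ∈ {1, 3, 5, 7, 9, 11, 13, 15, 17}
is fitted on **all** presences; the raw surface is renormalized to sum to 1;
the log-likelihood is the sum of log probabilities at presence cells
(repeats count multiply); and AICc = 2k − 2lnL + 2k(k+1)/(n−k−1) with n the
presence count, undefined (flagged, never thrown) when n ≤ k+1. The lowest
defined AICc wins; ties go to the smaller β (stronger smoothing).

ROC analysis uses background cells as pseudo-negatives — the standard
presence-only device. AUC is the exact Mann–Whitney concordance; the
threshold sweep runs over distinct observed scores with "suitable" meaning
score ≥ threshold; the habitat threshold maximizes sensitivity +
specificity, ties resolved toward the lower threshold (more predicted
habitat — conservative for conservation use). AUC labels: < 0.5 worse than
random, 0.5–0.7 no discrimination, > 0.7 better than random, 1 perfect.

Three replicate routines produce ensembles (mean/SD of AUC; cellwise
mean/SD cumulative maps): cross-validation with min(replicates, n) folds
(AUC on held-out presences), n-out-of-n bootstrap (AUC on training
presences), and seeded 75/25 subsampling (AUC on the 25% test split).
Replicates are capped at 100. With one replicate the SD maps are exactly
zero.

Variable importance:

* **Percent contribution** allocates each iteration's training-gain
  increase to variables proportionally to `Σ_j |Δλ_j|·s_j` over the
  variable's features (products split evenly between their two variables),
  normalized to 100. Sequential-update attribution has no exact meaning for
  a simultaneous-update solver; this is the documented approximation.
* **Permutation importance** permutes each variable's feature columns with
  one seeded row permutation, recomputes the training AUC from the linear
  predictor, takes `max(0, ΔAUC)` and normalizes to 100. Permuting the
  built columns (rather than rebuilding features from permuted raw values)
  keeps scalings and knots fixed — a deliberate, documented simplification.
* **Jackknife** refits with each variable alone and each variable omitted,
  reporting training gains next to the full-model gain (undefined
  omitted-gain for a single-variable model).

## Habitat maps and month comparison

Binary habitat is `cumulative ≥ threshold` over unmasked cells ("≥" so that
threshold 0 marks everything suitable — bit-exact area tests rely on this);
areas are cell counts times 6.25 km², and percent suitable is
100·suitable/total. Months are compared with the sample (Brownian) distance
correlation of jointly valid cell values: double-center each pairwise
absolute-difference matrix, then `dCor = sqrt(dCov²/√(dVar_A·dVar_B))`,
which is 0 when either surface is constant, 1 for affinely related
surfaces, and (in the population) 0 exactly under independence. Ensemble
comparisons use the replicate-mean cumulative maps.

## Synthetic scenarios

The generator emulates the study conditions: a ~7.5·10³ km² domain at
2.5 km resolution (36×42 cells, ≈1 200 sea cells after masking land plus a
2-cell near-shore exclusion ring), a west-coast shelf rising monotonically
past 200 m with seeded Gaussian relief and a deep basin (so all five
isobaths exist), lognormal chlorophyll fields with seasonal means
1.6–3.6 mg m⁻³, SST with a meridional gradient and seasonal offsets
(August warmest, October coldest, means ≈11–15 °C), and monthly presence
counts defaulting to 90/554/221/19 for July–October. The true suitability
surface is a Gibbs density driven by distance to shore and to the 150/200 m
isobaths, chlorophyll and SST — the variables a correct analysis should
rank as important. Sightings are drawn from truth × effort and jittered
uniformly within the cell so thinning distances are continuous; the effort
field decays with distance from a "port" on the west coast, reproducing the
clustered-ANN signature of whale-watch effort. A null scenario (all truth
coefficients zero) supports chance-level AUC checks.

What the generator does **not** emulate: tidal and gyre circulation, prey
(copepod) dynamics, inter-annual variability, observation error in
positions, or mixed-resolution source rasters (fields are generated
directly at 2.5 km). Passing recovery tests therefore demonstrates that the
estimator recovers a known exponential-family truth under realistic sample
sizes and effort bias — not that any particular real-world inference is
correct.

## Test and run sizes

The test suite and examples run on reduced problem sizes chosen as the
package's own desk-scale defaults: the 36×42 default grid, 10
cross-validation folds in the recovery checks (200 presences, fixed seeds),
and 500 presences for the AICc-ordering check — the smallest size at which
the near-unpenalized comparison fit (β = 0.01, ~250 active features) still
has a defined AICc. The full four-month pipeline at its protocol defaults
(100 replicates, 9-value β grid, jackknife on) completes in a few minutes
on one CPU.

## Known limitations

* The optimizer reproduces the model class, not any particular legacy
  implementation; λ values and derived importance numbers are comparable in
  meaning but not numerically interchangeable with other Maxent software.
* Percent contribution depends on the optimization path (as it does in any
  implementation); only its ranking should be interpreted.
* With perfectly separating features and β = 0 the likelihood is unbounded;
  fits then stop at the iteration cap with `converged=False` and a gain
  approaching the analytic limit `log(N_background/N_active)`.
* The ANN expectation uses the uncorrected classical formula; with small n
  or elongated study areas its bias is inherited by the thinning distance.
* Presence-only AUC against background pseudo-negatives is rank-based and
  bounded below 1 by the background overlap; values are comparable across
  months of one study, not across studies.
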