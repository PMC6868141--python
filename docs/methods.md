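# Methods

This note records the models, the defaults and the numerical choices the
package makes, and what its synthetic-data tests do and do not establish
about behaviour on real data.

## Grids and landscapes

The default grid is planar equal-area: cells are squares of `cell_size` km
(default 50 km, roughly a half-degree cell at mid latitudes), areas are
counts × `cell_size²`, distances are Euclidean centre-to-centre.  A
geographic mode (cell size in degrees, cos-latitude area weighting) exists
for realism but is not the testing default, because it adds projection
detail without changing any algorithmic property under test.

Synthetic landscapes are built from Gaussian-filtered white noise
(`scipy.ndimage.gaussian_filter`) standardized to unit variance, giving a
controllable autocorrelation length in cells:

* **Bathymetry** — relief field × 800 m, shifted so the configured sea
  fraction of cells falls below 0 m; `sea_fraction=0` shifts the minimum
  to 0 instead (all land).
* **Temperature** — a north–south annual-mean gradient (14 °C top to
  bottom by default) plus a seasonal cosine cycle (half-amplitude 9 °C)
  plus a smooth spatial anomaly (SD 2.5 °C); tmax − tmin is a smooth,
  strictly positive diurnal-range field, which enforces tmax ≥ tmin by
  construction.
* **Precipitation** — a log-normal wetness field (log-SD 0.6 around
  80 mm/month) with a seasonal modulation, clipped at 0.
* **Land use** — five correlated Gaussian fields pushed through a softmax
  with class-specific offsets (forest and other natural land favoured,
  settled land rare).  The softmax guarantees the five fractions close to
  1 in every cell exactly.
* **Regions** — contiguous column bands holding near-equal numbers of
  land cells stand in for native biogeographic regions.

These defaults aim at a temperate-to-subtropical gradient with plausible
magnitudes; they were chosen once as the study conditions for all tests.

### Scenarios

Each policy arm ("mitigation", "baseline") at two horizons (defaults 40
and 60 years from present) modifies the base landscape two ways:

* **Climate** — a spatially modulated warming increment (defaults:
  mitigation 1.0/1.5 °C at h1/h2, baseline 2.0/3.5 °C, spatial modulation
  SD 0.25 of the increment) and a relative precipitation change of −3%
  per degree.  Mitigation may never warm more than baseline; h2 change is
  at least h1 change — violations are configuration errors.
* **Land use** — mass-conserving transfers inside contiguous patches
  selected as the top quantile of a smooth priority field (h1 patches
  nest inside h2 patches by construction).  Mitigation converts more land
  (defaults 12/18% of land cells vs 8/12%) and converts other natural
  land and pasture into forest and cropland (afforestation + bioenergy);
  baseline converts other natural land and forest into cropland and
  pasture.  60% of the source-class fraction moves inside a patch.

The counterfactual variants are assembled exactly: LU keeps the current
climate arrays, CC keeps the current land-use array, LUCC reuses the LU
land use and the CC climate cell-for-cell.  Real land-use downscaling
allocates conversion by attainable yield; the patch rule does not emulate
yield surfaces, only the spatial contiguity and the arm contrast.

### Species and sampling bias

A species' true suitability is `expit(intercept + Σ a_j z_j + Σ b_j z_j²)`
over a random subset (default 3) of the 24 candidate predictors,
standardized over land cells of the base landscape; quadratic
coefficients are drawn negative (unimodal niches), and the intercept is
bisected so that mean suitability over the native region hits a target
prevalence (default uniform in 0.15–0.45).  Occurrence records are drawn
with replacement with probability ∝ suitability × effort, where the
effort surface `exp(strength × smooth field)` is shared by the whole
community — the situation target-group background correction assumes.
Traits (body mass, maturity, longevity, diet, growth form, dispersal
syndrome) come from per-taxon distributions with ecologically plausible
medians.

Because the generating link is logistic while the fitted model is
log-linear, the SDM is deliberately slightly misspecified; rank recovery
is still high (see below), which is the realistic regime.

## Bioclim variables

Monthly mean temperature is (tmin + tmax)/2.  Quarters are running
three-month windows with December–January wraparound; ties go to the
earliest window.  bio4 is 100 × the population SD of monthly means; bio15
is the precipitation CV with the mean floored at 1 mm; bio3 is defined 0
when the annual range is 0.  The quarter convention is the dominant
WorldClim dialect; it is the only dialect implemented, and the layer
order/names `bio1..bio19` are fixed.  Permuting months leaves the
order-free layers unchanged but may change quarter-based layers (this is
documented behaviour, asserted only for the order-free set).

## Predictor filtering

Admissibility of a subset: no pair with |Pearson r| ≥ `r_max` (0.70), and
every member's VIF — computed *within that subset*, after pair exclusion,
matching the stated filter order — below `vif_max` (5).  A zero-variance
column has undefined correlations and is treated as an excluded pair.
Enumeration prunes the lattice: every admissible set is an independent
set of the pairwise-conflict graph, so the search starts from that
graph's maximal independent sets (maximal cliques of the complement via
networkx) and descends only while a VIF violation remains, removing one
member at a time with memoization; survivors nested in other survivors
are pruned.  Because VIF can only fall when a set shrinks, the descent
must branch on *every* member of a violating set, not only the violating
ones — this is what makes the pruned search provably equal to brute-force
enumeration (tested for pools up to 12).  The conceptual total 2^p is
reported; pools above 24 predictors are rejected.  Correlations are
evaluated on the species' background sample within its native region (the
model's fitting domain; a global option would be a one-line change).

## The SDM

Features: a linear and a quadratic term per predictor, min–max scaled to
[0, 1] over the fitting sample (presences ∪ background); at prediction
time features are clamped to the training bounds.  With presences
appended to the background (target-group semantics; a flag excludes
them), weights λ minimize

    −(1/m) Σ_pres λ·f(x) + log Σ_bg w(x) e^{λ·f(x)} + Σ_j β_j |λ_j|,

with β_j = β · s_j/√m, s_j the feature SD over presences floored at
10⁻³ (the floor keeps near-constant features penalizable).  The convex
problem is solved by splitting λ into positive and negative parts and
running L-BFGS-B with analytic gradients (ftol 10⁻¹²); weights below
10⁻⁸ are snapped to 0, and k counts the non-zero weights.  The
log-likelihood is the Gibbs likelihood with the weighted background as
base measure; AICc = 2k − 2LL + 2k(k+1)/(m−k−1), reported +∞ when
m ≤ k+1 or LL is not finite.

Two-stage selection: all candidate subsets at β = 0, keep the AICc
minimum; refit that subset over the 31-value grid 0–15 in 0.5 steps; ties
break by smaller k, then smaller β, then lexicographic subset order.

Suitability output uses the complementary log-log transform
`1 − exp(−exp(H + η))`, where η = λ·f(x) − log Σ_bg e^{λ·f} is the
*uniform-base* normalized linear predictor and H the entropy of the
uniform-base raw distribution.  The uniform base (rather than the
weighted one) keeps exp(H + η) of order 1 so the output does not saturate;
the transform is strictly monotone in the raw output, so thresholds and
the Boyce index — both rank-based — are invariant to this choice.  The
exponent is capped at 30 purely to avoid overflow warnings.

Background size defaults to 10,000 draws in the API; the pipeline and
tests use 600–2,000, which profiling showed is where the recovery curves
flatten at these grid sizes.

## Evaluation

Folds: presences and background are split into k = 10 near-equal random
folds separately; the model (fixed subset and β) is refit per calibration
split.  CBI: 101 windows of width 10% of the background suitability
range; P is the presence fraction per window, E the (multiplicity-
weighted) background fraction; windows with E = 0 are dropped and the
index is the Spearman correlation of P/E with the window midpoint.
Undefined cases (single-valued presences, constant P/E, fewer than two
usable windows) return NaN; a species with more than 3 undefined folds is
dropped.  The 95% CI of the fold-mean is Student-t across folds (a
bootstrap over folds is available behind a flag); retention requires the
lower bound > 0.

Two calibration facts worth knowing.  First, the index is exactly
invariant to affine transforms of suitability but only nearly invariant
to general monotone transforms, because the windows live on the raw
scale; the rank-based core keeps the drift below ~0.05 in tests.  Second,
for a chance model the per-fold CBI is noisy (the overlapping windows
leave roughly ten effective degrees of freedom, giving an SD near 0.3
regardless of sample size), so "chance ≈ 0" is a statement about the mean
across replicates, which is what the tests assert; retention is protected
from this noise by the CI across folds.

The habitat threshold per fold is the largest observed calibration-
presence suitability t with sensitivity ≥ 90%; the final threshold is the
fold average, which guarantees ≥ 90% sensitivity per fold exactly and
≳ 85% pooled (averaging across folds can cost a few points).

## Habitat dynamics

Habitat = suitability ≥ threshold ∧ native region ∧ land.  The
connectivity filter labels connected components (8-connectivity, so
diagonal land bridges count; 4-connectivity is a parameter) of the
paleo landmass (elevation ≥ −130 m) and keeps habitat only on components
containing at least one occurrence cell.  PFH-CDD intersects the future
suitable map with the set of cells whose centre lies within D km of a
previously occupied cell (Euclidean distance transform × cell size, with
a 10⁻⁹ km tolerance against float rounding); D = 0 therefore keeps
exactly the previously occupied cells that stay suitable.  Projections
chain: the h2 buffer grows from the h1 PFH-CDD with the h1→h2 dispersal
distance, per driver set.

Dispersal: D = d_g (t1 − t0)/g exactly.  d_g comes from a generic
log-linear allometry — log₁₀ d_g = intercept + slope·log₁₀(mass) +
diet/growth-form/syndrome offsets — whose per-taxon default coefficients
are illustrative (plausible orderings: birds > mammals > reptiles >
amphibians; wind/animal-dispersed plants > unassisted) and fully
overridable; an OLS helper calibrates a rule from a log-log
trait/dispersal table.  Generation length defaults to
g = maturity + z·(longevity − maturity) with z = 0.5 for animals and a
growth-form lookup for plants; both are explicit configuration, not
fitted constants.

## Attribution

With H0 the current map and LU/CC/LUCC the counterfactual projections:
lost = H0 ∧ ¬LUCC, split into lost-to-land-use (¬LU ∧ CC), lost-to-
climate (¬CC ∧ LU) and lost-combined (the remainder — both pixels
unsuitable under either single driver and pixels suitable under each
single driver but not both); gains mirror this with roles reversed.  The
eight categories (plus unchanged suitable/unsuitable) partition the
domain, so per-driver areas sum to totals identically — asserted, not
approximate.  Areas are cell-area-weighted sums.

## Reporting statistics

The area GLMM is y ~ Gamma(shape α, mean μ), log μ = Xβ + offset + b_i,
offset = log(current area + 10⁻⁶), response = area + 10⁻⁶, b_i ~ N(0, σ²)
per species.  Fixed effects: intercept, arm (reference: baseline),
horizon (reference: first), their interaction, SSP label (reference:
SSP2), replicate, taxon (reference: vascular plant); single-level factors
are dropped with a warning.  No installed Python library fits this family
with a random intercept, so the marginal likelihood is computed
in-package: per species the integrand is re-centred at its posterior mode
(Newton steps, vectorized across species) and integrated with 15-point
adaptive Gauss–Hermite quadrature; (β, log α, log σ) are optimized by
BFGS with a Nelder–Mead polish on stall, and Wald SEs come from the
inverse central-difference Hessian at the optimum.  Doubling all areas
shifts the likelihood by a constant, leaving estimates bit-identical —
the offset-correctness check.  In recovery simulations at 500 species the
Wald CIs show near-nominal (93–97%) coverage; at much smaller species
counts they run a few points below nominal, as expected for ML (not
REML-like) variance estimates.

The regional regressions are OLS of logit(y) on x, with y clamped into
(ε, 1−ε), ε = 10⁻⁶ symmetric (mirroring the GLMM floor), and x
logit-transformed when it is itself a proportion (converted-land
fraction) or raw when it is a temperature difference; adjusted R² and a
95% prediction interval are reported via statsmodels.

GCM-style replicate spread is emulated in the pipeline by seeded
perturbations of the scenario warming amounts; replicates enter the GLMM
as a factor exactly as a climate-model label would.

## Pipeline choices and problem sizes

The demo/testing configuration is a 26×26–30×30 grid, 6–12 species, 600–
1,000 background draws, 5–10 folds and 2 replicates; recovery experiments
use a 50×50 grid, ~200 thinned presences and 2,000 background draws, and
the GLMM simulations 300–500 species.  These sizes sit where the recovery
metrics plateau in profiling.  Two pipeline-specific choices:

* **Background density.**  With only a handful of species per taxon, the
  empirical target-group record density degenerates toward the focal
  species' own distribution, cancelling the niche signal itself rather
  than the survey bias.  The pipeline therefore defaults to the
  community effort surface — the large-community limit of target-group
  density — and offers `background_density="record_counts"` for the
  empirical estimate.
* **Candidate-set cap.**  The enumerated maximal sets are capped
  (default 20, lexicographic order) to bound the stage-1 fitting cost.

## What the synthetic tests do and do not show

They establish that every algorithmic component does what it claims:
filters match brute force, the solver reaches the convex optimum, the
decomposition is an exact partition, the GLMM recovers known
coefficients with near-nominal coverage, ground-truth niches are
recovered (replicate-mean rank correlation ≈ 0.96) and shared sampling
bias is cancelled by the biased background.  They do not establish
performance on real occurrence data: real niches are not
linear-quadratic, real survey effort is not shared exactly across a
target group, land-use change is allocated by yield rather than by
contiguous patches, and real climate deltas have GCM-specific spatial
structure.  Headline global percentages from real-data studies are
therefore out of reach of this artifact by design.

## Known limitations

* Single bioclim dialect; no hinge/product features, no AUC/TSS.
* The chance-level CBI spread (window overlap) makes single-fold CBI a
  noisy statistic; retention decisions should always go through the CI.
* The allometry defaults are illustrative; scientific use requires
  calibrated coefficients via `fit_dispersal_rule` or config.
* ML (not REML) variance components give slightly anticonservative Wald
  CIs for small species counts.
* The land-use transfer rule conserves mass but ignores attainable-yield
  allocation.
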