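# habishift

Dispersal-constrained species distribution projections with land-use /
climate driver attribution — a desk-scale, fully synthetic re-creation of
the modelling chain used in global assessments of how climate policy and
its land-based side effects (bioenergy cropland, afforestation) reshape
species' suitable habitat.

The pipeline answers, for each species on a gridded landscape: *how much
suitable habitat is lost or gained under a mitigation versus a baseline
future, and how much of that change is due to land-use change, climate
change, or their combination?*

## The modelling chain

1. **Synthetic landscapes** — monthly tmin/tmax/precipitation, five
   land-use fractions (cropland, pasture, forest, other natural land,
   settled land) closed on the simplex, bathymetry and native-region
   labels, all spatially autocorrelated and seed-reproducible.  Paired
   future scenarios vary land use only (LU), climate only (CC) or both
   (LUCC), at two horizons and two policy arms; the mitigation arm warms
   less but converts more land.
2. **Bioclim features** — the 19 standard bioclimatic variables from
   monthly climate (running three-month quarters with wraparound).
3. **Predictor filtering** — all 2^p subsets of the candidate pool are
   conceptually screened: subsets containing a pair with |Pearson r| ≥
   0.70 or a member with within-subset VIF ≥ 5 are dropped, nested subsets
   are pruned, and the maximal admissible sets survive (the lattice is
   pruned, not materialized).
4. **MaxEnt-equivalent SDM** — an L1-penalized log-linear
   (Gibbs) model over linear + quadratic features scaled to [0, 1], with
   per-feature penalties `β · s_j / √m`, normalized over a target-group
   biased background that cancels shared survey bias.  Model selection is
   two-stage by AICc (k = non-zero weights): best predictor subset at
   β = 0, then the best of the 31-value grid β = 0, 0.5, …, 15.
5. **Evaluation & thresholding** — 10-fold cross-validated continuous
   Boyce index (CBI ∈ [−1, 1]); species are retained when the 95% CI of
   the fold-mean CBI is above zero.  The habitat threshold is the fold
   average of the 90%-sensitivity cut-off.
6. **Habitat dynamics** — boolean habitat maps (threshold + native-range
   clip + land), a paleo-coastline connectivity filter (habitat on
   landmasses not connected at a −130 m sea level to any occupied
   landmass is discarded), trait-based dispersal
   `D = d_g · (t1 − t0) / g` (allometric per-generation distance d_g,
   generation length g), and chained dispersal-constrained projection:
   future suitable cells within distance D of the previously occupied
   habitat, horizon by horizon and driver set by driver set.
7. **Attribution** — per pixel, loss (habitat now, absent from LUCC) is
   attributed to land use (absent from LU, present in CC), climate
   (absent from CC, present in LU) or their combination (the remainder);
   gains mirror this.  The six categories partition change exactly.
8. **Reporting statistics** — a gamma GLMM (log link) on lost/gained
   areas with `log(current area)` offset, fixed effects for scenario arm,
   horizon, their interaction, SSP label, climate-replicate and taxon,
   and a species random intercept (adaptive Gauss–Hermite maximum
   likelihood, Wald tests); plus logit-scale OLS regressions of regional
   loss proportions on driver covariates.

Everything runs on synthetic data with known ground truth, so each stage
is checked against what it should recover: the true niches, the generating
predictor subsets, the CBI's calibration bounds, the attribution truth
table, and the GLMM's simulated coefficients.

## A worked example

`examples/03_project_and_attribute.py` projects one synthetic plant
species (known niche over bio1, bio5 and forest fraction) through both
policy arms and decomposes its habitat change:

```
vascular_plant: d_g = 0.00 km/generation, g = 2.0 yr -> D(h1) = 0 km, D(h1->h2) = 0 km
current habitat area: 680,000 km2
       arm horizon  lost %  lost_LU %  lost_CC %  lost_comb %  gained %
mitigation      h1    18.4        0.0       18.4          0.0       0.0
mitigation      h2    19.5        0.0       19.5          0.0       0.0
  baseline      h1    32.7        0.4       28.7          3.7       0.0
  baseline      h2    42.3        1.5       34.9          5.9       0.0
```

Read: this poorly dispersing plant cannot colonize new habitat (gain 0),
loses far less under mitigation (19.5% by the second horizon) than under
baseline (42.3%), and its losses are dominated by climate, with land-use
and combined effects appearing under the stronger-warming baseline.  The
three driver columns always sum to the total because the decomposition is
an exact partition.

The other example scripts cover landscape/scenario generation (`01`), the
full per-species SDM fit with CBI evaluation (`02`), the gamma GLMM on
simulated area records (`04`), and the end-to-end pipeline with its CSV
outputs (`05`).  A thin CLI wraps the main stages:
`habishift run --config cfg.yaml --seed 1 --out rundir`.

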