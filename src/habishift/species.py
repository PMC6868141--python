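"""Synthetic species with known suitability ground truth and biased sampling.

Each generated species has a true suitability surface: a logistic function of
linear and quadratic terms in a small, known subset of the 24 candidate
predictors (5 land-use fractions + 19 bioclim layers), standardized over the
land cells of the base landscape.  Occurrence records are then sampled inside
the species' native region with probability proportional to true suitability
times a shared "survey effort" bias surface, emulating the spatial sampling
bias of large occurrence databases.  Because the bias surface is returned
with each occurrence set, downstream code can build the target-group biased
background that cancels the shared bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .bioclim import BIOCLIM_NAMES, compute_bioclim
from .landscapes import LANDUSE_CLASSES, LandscapeBundle

TAXON_GROUPS = ("vascular_plant", "amphibian", "reptile", "bird", "mammal")

PREDICTOR_NAMES = tuple(f"lu_{c}" for c in LANDUSE_CLASSES) + BIOCLIM_NAMES

GROWTH_FORMS = ("tree", "shrub", "herb", "graminoid")
DISPERSAL_SYNDROMES = ("wind", "animal", "ballistic", "unassisted")

#: per-taxon trait sampling parameters: log10 body-mass mean/sd (g),
#: female maturity mean (yr), max longevity multiplier over maturity
_TRAIT_PARAMS = {
    "vascular_plant": (1.0, 1.0, 5.0, 8.0),
    "amphibian": (1.2, 0.5, 2.0, 5.0),
    "reptile": (2.0, 0.8, 3.0, 6.0),
    "bird": (1.8, 0.6, 1.5, 8.0),
    "mammal": (3.0, 1.2, 2.5, 7.0),
}


@dataclass
class TraitRecord:
    """Life-history traits feeding the dispersal allometry."""

    body_mass: float  # g
    diet_carnivorous: bool = False
    growth_form: str | None = None  # plants only
    dispersal_syndrome: str | None = None  # plants only
    female_maturity: float = 2.0  # years
    max_longevity: float = 10.0  # years

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        if not (0 < self.female_maturity < self.max_longevity):
            raise ValueError("need 0 < female_maturity < max_longevity")


@dataclass
class TrueSpecies:
    """Ground-truth generating model for one synthetic species."""

    species_id: str
    taxon_group: str
    predictor_names: tuple  # the known generating subset
    linear_coefs: np.ndarray
    quadratic_coefs: np.ndarray
    intercept: float
    standardize_mean: np.ndarray  # over land cells of the base landscape
    standardize_sd: np.ndarray
    prevalence: float
    traits: TraitRecord
    native_region: int


@dataclass
class OccurrenceSet:
    """Raw presence records of one species on the grid."""

    species_id: str
    records: np.ndarray  # (n, 2) of (row, col), with repeats allowed
    thinned: np.ndarray  # bool per record: first record in its cell
    bias_surface: np.ndarray | None = None  # survey-effort weight layer used

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class SpeciesConfig:
    """Knobs for the synthetic community."""

    n_true_predictors: int = 3
    candidate_predictors: tuple = ("bio1", "bio5", "bio6", "bio12", "bio15",
                                   "lu_forest", "lu_cropland", "lu_other_natural")
    linear_coef_sd: float = 1.2
    quadratic_coef_scale: float = 0.6  # drawn negative: unimodal niches
    prevalence_range: tuple[float, float] = (0.15, 0.45)
    n_records: int = 200
    bias_strength: float = 1.0  # 0 disables sampling bias
    bias_scale: float = 5.0  # autocorrelation length of the effort field
    taxon_groups: tuple = TAXON_GROUPS


def predictor_stack(landscape: LandscapeBundle) -> tuple[tuple, np.ndarray]:
    """All 24 candidate predictors (5 land-use + 19 bioclim) as one stack.

    Returns ``(names, values)`` with values of shape (24, n_rows, n_cols).
    """
    bc = compute_bioclim(landscape.tmin, landscape.tmax, landscape.prec)
    values = np.concatenate([landscape.landuse, bc.layers], axis=0)
    return PREDICTOR_NAMES, values


def true_suitability(species: TrueSpecies, landscape: LandscapeBundle) -> np.ndarray:
    """Evaluate the species' generating suitability on any landscape.

    Standardization uses the moments stored at generation time so that the
    same niche function applies consistently under scenario landscapes.
    """
    names, stack = predictor_stack(landscape)
    idx = [names.index(p) for p in species.predictor_names]
    x = stack[idx]  # (p, nr, nc)
    z = (x - species.standardize_mean[:, None, None]) / species.standardize_sd[:, None, None]
    eta = species.intercept + np.tensordot(species.linear_coefs, z, axes=1)
    eta = eta + np.tensordot(species.quadratic_coefs, z**2, axes=1)
    return expit(eta)


def _sample_traits(rng: np.random.Generator, taxon: str) -> TraitRecord:
    lm, ls, mat_mean, long_mult = _TRAIT_PARAMS[taxon]
    mass = float(10 ** rng.normal(lm, ls))
    maturity = float(np.clip(rng.gamma(4.0, mat_mean / 4.0), 0.2, None))
    longevity = maturity * (1.0 + float(rng.gamma(3.0, long_mult / 3.0)))
    rec = TraitRecord(
        body_mass=mass,
        diet_carnivorous=bool(rng.random() < 0.3),
        female_maturity=maturity,
        max_longevity=longevity,
    )
    if taxon == "vascular_plant":
        rec.growth_form = GROWTH_FORMS[rng.integers(len(GROWTH_FORMS))]
        rec.dispersal_syndrome = DISPERSAL_SYNDROMES[rng.integers(len(DISPERSAL_SYNDROMES))]
    return rec


def _calibrate_intercept(eta0: np.ndarray, target: float) -> float:
    """Offset so that mean logistic suitability over cells hits ``target``."""
    lo, hi = -30.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expit(eta0 + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_species(
    base: LandscapeBundle,
    n_species: int,
    config: SpeciesConfig | None = None,
    seed: int = 0,
) -> list[tuple[TrueSpecies, OccurrenceSet]]:
    """Generate species with known niches and spatially biased occurrences.

    Presences are sampled with replacement with probability proportional to
    (true suitability x bias surface) over the land cells of the species'
    native region.  With ``bias_strength = 0`` the bias surface is flat and
    sampling is proportional to suitability alone.
    """
    from .landscapes import _smooth_field  # shared field generator

    cfg = config or SpeciesConfig()
    rng = np.random.default_rng(seed)
    land = base.land_mask
    if cfg.n_records > int(land.sum()):
        raise ValueError("requested records exceed available land cells")

    names, stack = predictor_stack(base)
    flat = stack.reshape(len(names), -1)

    # one shared survey-effort surface per community (target-group semantics)
    if cfg.bias_strength > 0:
        bias = np.exp(cfg.bias_strength * _smooth_field(rng, base.grid.shape, cfg.bias_scale))
    else:
        bias = np.ones(base.grid.shape)
    bias = bias / bias[land].mean()

    regions = base.region_labels
    out: list[tuple[TrueSpecies, OccurrenceSet]] = []
    for i in range(n_species):
        taxon = cfg.taxon_groups[i % len(cfg.taxon_groups)]
        native = regions[int(rng.integers(len(regions)))]
        region_mask = base.region_mask(native)
        preds = tuple(sorted(
            str(p) for p in
            rng.choice(cfg.candidate_predictors, cfg.n_true_predictors, replace=False)
        ))
        idx = [names.index(p) for p in preds]
        xs = flat[idx][:, land.ravel()]
        mu = xs.mean(axis=1)
        sd = np.maximum(xs.std(axis=1), 1e-9)

        lin = rng.normal(0.0, cfg.linear_coef_sd, len(preds))
        quad = -np.abs(rng.normal(0.0, cfg.quadratic_coef_scale, len(preds)))
        prevalence = float(rng.uniform(*cfg.prevalence_range))

        z_native = (flat[idx][:, region_mask.ravel()] - mu[:, None]) / sd[:, None]
        eta0 = lin @ z_native + quad @ (z_native**2)
        intercept = _calibrate_intercept(eta0, prevalence)

        sp = TrueSpecies(
            species_id=f"sp{i:04d}",
            taxon_group=taxon,
            predictor_names=preds,
            linear_coefs=lin,
            quadratic_coefs=quad,
            intercept=intercept,
            standardize_mean=mu,
            standardize_sd=sd,
            prevalence=prevalence,
            traits=_sample_traits(rng, taxon),
            native_region=int(native),
        )

        suit_native = expit(eta0 + intercept)
        w = suit_native * bias[region_mask]
        w = w / w.sum()
        cells = np.flatnonzero(region_mask.ravel())
        draws = rng.choice(cells, size=cfg.n_records, replace=True, p=w)
        records = np.column_stack(np.unravel_index(draws, base.grid.shape))
        seen: set = set()
        thinned = np.zeros(len(records), dtype=bool)
        for j, rc in enumerate(map(tuple, records)):
            if rc not in seen:
                seen.add(rc)
                thinned[j] = True
        out.append((sp, OccurrenceSet(sp.species_id, records, thinned, bias)))
    return out
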