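"""Synthetic landscapes and counterfactual scenario bundles.

The generator emulates the gridded inputs a global habitat-change analysis
would normally assemble from climate, land-use and bathymetry data products:

* monthly minimum/maximum temperature and precipitation with a latitudinal
  gradient, a seasonal cycle and spatially autocorrelated noise;
* five land-use fractions (cropland, pasture, forest, other natural land,
  settled land) produced by a softmax of correlated Gaussian fields, which
  guarantees that the fractions close to 1 in every cell;
* bathymetry (negative = below present sea level) so that a paleo-coastline
  connectivity rule can be exercised;
* labelled "native region" partitions of the land surface.

Future scenarios come in two arms ("mitigation", "baseline") at two horizons
and three driver sets: land-use change only (LU, climate held at present),
climate change only (CC, land use held at present), and both (LUCC).  The
mitigation arm warms less but converts *more* land (bioenergy cropland and
afforestation), mirroring the qualitative contrast between stringent-policy
and no-policy futures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridSpec

LANDUSE_CLASSES = ("cropland", "pasture", "forest", "other_natural", "settled")

ARMS = ("mitigation", "baseline")
DRIVER_SETS = ("LU", "CC", "LUCC")
HORIZONS = ("h1", "h2")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Unit-variance Gaussian random field with autocorrelation length ``scale`` cells."""
    if scale <= 0:
        raise ValueError("autocorrelation scale must be > 0")
    f = gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="reflect")
    sd = f.std()
    if sd < 1e-12:  # degenerate tiny grids
        return np.zeros(shape)
    return (f - f.mean()) / sd


@dataclass
class LandscapeConfig:
    """Synthesis parameters for one landscape.

    Length scales are in cells; temperatures in deg C; precipitation in mm/month.
    """

    sea_fraction: float = 0.3
    relief_scale: float = 5.0  # autocorrelation length of the elevation field
    relief_amplitude: float = 800.0  # m (one field SD)
    temp_mean: float = 8.0  # annual mean at the grid's mid-latitude
    temp_lat_gradient: float = 14.0  # deg C increase from top row to bottom row
    temp_season_amp: float = 9.0  # seasonal half-amplitude of monthly means
    temp_noise_sd: float = 2.5  # SD of the spatial temperature anomaly
    temp_scale: float = 6.0
    diurnal_range: float = 9.0  # mean tmax - tmin
    diurnal_noise_sd: float = 2.0
    prec_mean: float = 80.0  # mm per month at grid scale
    prec_log_sd: float = 0.6  # log-scale SD of the spatial wetness field
    prec_scale: float = 5.0
    prec_season_amp: float = 0.5  # relative seasonal modulation (0..1)
    landuse_scale: float = 4.0
    landuse_sharpness: float = 1.5  # softmax temperature of the land-use fields
    landuse_bias: tuple[float, ...] = (0.0, 0.0, 0.6, 0.6, -2.5)
    n_regions: int = 2


@dataclass
class LandscapeBundle:
    """Gridded monthly climate, land-use fractions, bathymetry and region labels."""

    grid: GridSpec
    tmin: np.ndarray  # (12, n_rows, n_cols), deg C
    tmax: np.ndarray  # (12, n_rows, n_cols), deg C
    prec: np.ndarray  # (12, n_rows, n_cols), mm
    landuse: np.ndarray  # (5, n_rows, n_cols), fractions
    bathymetry: np.ndarray  # (n_rows, n_cols), m; negative = below sea level
    region: np.ndarray  # (n_rows, n_cols) int; -1 on sea cells

    @property
    def land_mask(self) -> np.ndarray:
        return self.bathymetry >= 0.0

    @property
    def region_labels(self) -> list[int]:
        labs = np.unique(self.region[self.land_mask])
        return [int(r) for r in labs if r >= 0]

    def region_mask(self, label: int) -> np.ndarray:
        return (self.region == label) & self.land_mask

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        if self.tmin.shape != (12, *self.grid.shape):
            raise ValueError("climate layers must have shape (12, n_rows, n_cols)")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin in some cell-month")
        if np.any(self.prec < 0):
            raise ValueError("negative precipitation")
        land = self.land_mask
        lu = self.landuse[:, land]
        if np.any(lu < -1e-9) or np.any(lu > 1 + 1e-9):
            raise ValueError("land-use fraction outside [0, 1]")
        if np.any(np.abs(lu.sum(axis=0) - 1.0) > 1e-9):
            raise ValueError("land-use fractions do not sum to 1 on a land cell")
        if np.any(self.region[land] < 0):
            raise ValueError("land cell without a region label")

    def copy(self) -> "LandscapeBundle":
        return LandscapeBundle(
            grid=self.grid,
            tmin=self.tmin.copy(),
            tmax=self.tmax.copy(),
            prec=self.prec.copy(),
            landuse=self.landuse.copy(),
            bathymetry=self.bathymetry.copy(),
            region=self.region.copy(),
        )


def generate_landscape(
    spec: GridSpec, config: LandscapeConfig | None = None, seed: int = 0
) -> LandscapeBundle:
    """Generate one landscape; a pure function of ``(spec, config, seed)``."""
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    shape = spec.shape
    nr, nc = shape

    # --- bathymetry: smooth relief shifted so ~sea_fraction of cells are below 0
    relief = _smooth_field(rng, shape, cfg.relief_scale) * cfg.relief_amplitude
    if cfg.sea_fraction <= 0:
        bathymetry = relief - relief.min()  # all land
    else:
        bathymetry = relief - np.quantile(relief, cfg.sea_fraction)

    # --- temperature: latitude gradient + seasonal cycle + shared spatial anomaly
    lat01 = (np.arange(nr) / max(nr - 1, 1))[:, None] * np.ones((1, nc))
    annual_mean = cfg.temp_mean + cfg.temp_lat_gradient * (lat01 - 0.5)
    anomaly = _smooth_field(rng, shape, cfg.temp_scale) * cfg.temp_noise_sd
    months = np.arange(12)
    season = -np.cos(2 * np.pi * (months + 0.5) / 12.0)  # min in Jan, max in Jul
    diurnal = cfg.diurnal_range + _smooth_field(rng, shape, cfg.temp_scale) * cfg.diurnal_noise_sd
    diurnal = np.clip(diurnal, 0.5, None)
    tmean = annual_mean[None] + cfg.temp_season_amp * season[:, None, None] + anomaly[None]
    tmin = tmean - diurnal[None] / 2.0
    tmax = tmean + diurnal[None] / 2.0

    # --- precipitation: log-normal wetness field with a seasonal modulation
    wet = np.exp(_smooth_field(rng, shape, cfg.prec_scale) * cfg.prec_log_sd)
    p_season = 1.0 + cfg.prec_season_amp * np.sin(2 * np.pi * (months + 0.5) / 12.0)
    prec = cfg.prec_mean * wet[None] * p_season[:, None, None]
    prec = np.clip(prec, 0.0, None)

    # --- land use: softmax over correlated Gaussian fields closes the simplex
    logits = np.stack(
        [
            _smooth_field(rng, shape, cfg.landuse_scale) * cfg.landuse_sharpness + b
            for b in cfg.landuse_bias
        ]
    )
    logits -= logits.max(axis=0, keepdims=True)
    expl = np.exp(logits)
    landuse = expl / expl.sum(axis=0, keepdims=True)

    # --- regions: contiguous column bands with near-equal land-cell counts
    land = bathymetry >= 0.0
    region = np.full(shape, -1, dtype=int)
    n_regions = max(1, cfg.n_regions)
    land_per_col = land.sum(axis=0).astype(float)
    cum = np.cumsum(land_per_col)
    total = cum[-1] if cum[-1] > 0 else 1.0
    col_region = np.minimum((cum - land_per_col / 2) / total * n_regions, n_regions - 1e-9)
    col_region = col_region.astype(int)
    region[:, :] = col_region[None, :]
    region[~land] = -1

    bundle = LandscapeBundle(
        grid=spec,
        tmin=tmin,
        tmax=tmax,
        prec=prec,
        landuse=landuse,
        bathymetry=bathymetry,
        region=region,
    )
    bundle.validate()
    return bundle


@dataclass
class ScenarioConfig:
    """Per-arm warming (deg C) and land-conversion intensity at each horizon.

    ``warming`` maps arm -> (h1, h2) temperature increments; ``conversion``
    maps arm -> (h1, h2) fraction of land cells placed inside change patches.
    The mitigation arm must warm no more than baseline at each horizon, and
    each arm's h2 change must be at least its h1 change.  The mitigation arm
    converts more land by default: its patches turn other natural land into
    forest (afforestation) and cropland (bioenergy), whereas baseline patches
    turn forest and other natural land into cropland and pasture.
    """

    horizon_years: tuple[float, float] = (40.0, 60.0)
    warming: dict = field(
        default_factory=lambda: {"mitigation": (1.0, 1.5), "baseline": (2.0, 3.5)}
    )
    conversion: dict = field(
        default_factory=lambda: {"mitigation": (0.12, 0.18), "baseline": (0.08, 0.12)}
    )
    prec_change_per_degree: float = -0.03  # relative precipitation change per deg C
    warming_pattern_sd: float = 0.25  # spatial modulation of the warming field
    patch_scale: float = 3.0  # autocorrelation length of conversion patches
    transfer_fraction: float = 0.6  # share of source classes moved inside a patch

    def validate(self) -> None:
        for arm in ARMS:
            if arm not in self.warming or arm not in self.conversion:
                raise ValueError(f"missing scenario arm {arm!r}")
        for d in (self.warming, self.conversion):
            for arm, (a1, a2) in d.items():
                if a2 < a1:
                    raise ValueError(f"h2 change below h1 change for arm {arm!r}")
                if a1 < 0:
                    raise ValueError("negative change amount")
        for h in (0, 1):
            if self.warming["mitigation"][h] > self.warming["baseline"][h]:
                raise ValueError("mitigation warming exceeds baseline warming")
        if self.horizon_years[1] <= self.horizon_years[0]:
            raise ValueError("horizons must be strictly increasing")


@dataclass
class ScenarioSet:
    """Current landscape plus LU/CC/LUCC variants per arm and horizon."""

    current: LandscapeBundle
    variants: dict  # (arm, horizon, driver) -> LandscapeBundle
    horizon_years: tuple[float, float]

    def get(self, arm: str, horizon: str, driver: str) -> LandscapeBundle:
        return self.variants[(arm, horizon, driver)]


def _apply_climate_change(
    base: LandscapeBundle, delta_t: float, pattern: np.ndarray, prec_per_degree: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    warm = delta_t * pattern
    tmin = base.tmin + warm[None]
    tmax = base.tmax + warm[None]
    prec = np.clip(base.prec * (1.0 + prec_per_degree * warm[None]), 0.0, None)
    return tmin, tmax, prec


def _apply_landuse_change(
    base: LandscapeBundle, patch_mask: np.ndarray, arm: str, transfer_fraction: float
) -> np.ndarray:
    """Mass-conserving class transfers inside ``patch_mask`` cells."""
    lu = base.landuse.copy()
    idx = {name: i for i, name in enumerate(LANDUSE_CLASSES)}
    if arm == "mitigation":
        sources = ("other_natural", "pasture")
        targets = {"forest": 0.6, "cropland": 0.4}  # afforestation + bioenergy crops
    else:
        sources = ("other_natural", "forest")
        targets = {"cropland": 0.7, "pasture": 0.3}
    moved = np.zeros(base.grid.shape)
    for s in sources:
        take = lu[idx[s]] * transfer_fraction * patch_mask
        lu[idx[s]] -= take
        moved += take
    for t, share in targets.items():
        lu[idx[t]] += moved * share
    return lu


def generate_scenarios(
    base: LandscapeBundle, config: ScenarioConfig | None = None, seed: int = 0
) -> ScenarioSet:
    """Build the LU / CC / LUCC counterfactual bundles for both arms and horizons.

    LU variants keep the current climate layers exactly; CC variants keep the
    current land use exactly; LUCC combines the LU land use and CC climate of
    the same arm and horizon (cell-by-cell identical arrays).
    """
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    # one spatial warming pattern and one conversion-priority field per arm,
    # shared between horizons so h1 patches nest inside h2 patches
    pattern = 1.0 + cfg.warming_pattern_sd * _smooth_field(rng, base.grid.shape, 4.0)
    pattern = np.clip(pattern, 0.1, None)
    priority = {arm: _smooth_field(rng, base.grid.shape, cfg.patch_scale) for arm in ARMS}

    land = base.land_mask
    variants: dict = {}
    for arm in ARMS:
        for hi, horizon in enumerate(HORIZONS):
            delta_t = cfg.warming[arm][hi]
            conv = cfg.conversion[arm][hi]
            tmin, tmax, prec = _apply_climate_change(
                base, delta_t, pattern, cfg.prec_change_per_degree
            )
            if conv > 0 and land.any():
                thr = np.quantile(priority[arm][land], 1.0 - min(conv, 1.0))
                patch = (priority[arm] >= thr) & land
            else:
                patch = np.zeros(base.grid.shape, dtype=bool)
            lu = _apply_landuse_change(base, patch, arm, cfg.transfer_fraction)

            lu_bundle = replace(base.copy(), landuse=lu)
            cc_bundle = replace(base.copy(), tmin=tmin, tmax=tmax, prec=prec)
            lucc_bundle = replace(base.copy(), landuse=lu.copy(), tmin=tmin.copy(),
                                  tmax=tmax.copy(), prec=prec.copy())
            for b in (lu_bundle, cc_bundle, lucc_bundle):
                b.validate()
            variants[(arm, horizon, "LU")] = lu_bundle
            variants[(arm, horizon, "CC")] = cc_bundle
            variants[(arm, horizon, "LUCC")] = lucc_bundle

    return ScenarioSet(current=base, variants=variants, horizon_years=cfg.horizon_years)
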