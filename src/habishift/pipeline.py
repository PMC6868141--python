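"""End-to-end orchestration: simulate -> model -> project -> attribute -> report.

The pipeline wires every stage together on synthetic inputs: generate a
landscape and a species community, build biased target-group backgrounds,
enumerate admissible predictor subsets, run the two-stage AICc MaxEnt
selection, retain species by cross-validated Boyce index, derive
90%-sensitivity thresholds, project dispersal-constrained habitat under
every scenario arm / horizon / driver set (with seeded climate-perturbation
replicates standing in for the general-circulation-model factor), decompose
change into drivers, and fit the gamma GLMMs on the tidy area records.

Everything is a pure function of the configuration and seed; re-running with
the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .attribution import decompose_change, summarize_areas
from .dispersal import default_allometry, estimate_dispersal
from .evaluation import evaluate_species, sensitivity_threshold
from .glmm import fit_area_glmm
from .grids import GridSpec
from .habitat import project_species
from .landscapes import (
    ARMS,
    HORIZONS,
    LandscapeConfig,
    ScenarioConfig,
    generate_landscape,
    generate_scenarios,
)
from .maxent import (
    predict_on_landscape,
    prepare_occurrences,
    sample_bias_background,
    select_model,
)
from .predictors import enumerate_candidate_sets
from .species import SpeciesConfig, generate_species, predictor_stack


@dataclass
class PipelineConfig:
    """One run's worth of knobs; loadable from YAML."""

    n_rows: int = 30
    n_cols: int = 30
    cell_size: float = 50.0
    n_species: int = 12
    n_background: int = 1000
    min_records: int = 30
    k_folds: int = 10
    predictor_pool: tuple = (
        "bio1", "bio4", "bio5", "bio6", "bio12", "bio15",
        "lu_cropland", "lu_forest", "lu_other_natural",
    )
    max_candidate_sets: int = 20
    background_density: str = "effort_surface"  # or "record_counts"
    beta_grid_max: float = 15.0
    beta_grid_step: float = 0.5
    ssps: tuple = ("SSP2",)
    ssp_conversion_scale: dict = field(default_factory=lambda: {"SSP2": 1.0})
    n_replicates: int = 2
    replicate_warming_jitter: float = 0.15  # deg C SD across replicates
    seed: int = 0
    landscape: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    species: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SpeciesOutcome:
    species_id: str
    taxon_group: str
    region: str
    m: int
    pass_min_records: bool
    selected_set: tuple = ()
    selected_beta: float = np.nan
    cbi_mean: float = np.nan
    cbi_ci_low: float = np.nan
    retained: bool = False
    threshold: float = np.nan
    d_g: float = np.nan
    generation: float = np.nan
    D_h1: float = np.nan
    D_h2: float = np.nan
    current_area: float = np.nan


@dataclass
class PipelineResult:
    config: PipelineConfig
    outcomes: list
    records: pd.DataFrame
    glmm_lost: object = None
    glmm_gained: object = None
    manifest: dict = field(default_factory=dict)


def _taxon_density(occurrence_sets, taxa, grid_shape, smooth_sigma=1.0) -> dict:
    """Target-group record density per taxon: counts of all raw records,
    lightly smoothed so backgrounds have support around survey clusters."""
    density = {}
    for taxon in set(taxa):
        counts = np.zeros(grid_shape)
        for occ, t in zip(occurrence_sets, taxa):
            if t != taxon:
                continue
            np.add.at(counts, (occ.records[:, 0], occ.records[:, 1]), 1.0)
        density[taxon] = gaussian_filter(counts, sigma=smooth_sigma)
    return density


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = GridSpec(cfg.n_rows, cfg.n_cols, cfg.cell_size)

    base = generate_landscape(grid, LandscapeConfig(**cfg.landscape), seed=cfg.seed)
    sp_cfg = SpeciesConfig(**cfg.species)
    community = generate_species(base, cfg.n_species, sp_cfg, seed=cfg.seed + 1)
    species_list = [sp for sp, _ in community]
    occ_list = [occ for _, occ in community]
    taxa = [sp.taxon_group for sp in species_list]
    if cfg.background_density == "record_counts":
        density = _taxon_density(occ_list, taxa, grid.shape)
    else:
        # large-community limit of the target-group density: the shared
        # survey-effort surface (small communities estimate effort poorly,
        # collapsing the background onto the focal species' own niche)
        effort = occ_list[0].bias_surface
        density = {t: effort for t in set(taxa)}

    # scenario sets per (ssp, replicate): seeded warming jitter emulates the
    # across-climate-model spread entering the GLMM as a replicate factor
    scen_base = ScenarioConfig(**cfg.scenario)
    scenario_sets = {}
    for s_i, ssp in enumerate(cfg.ssps):
        scale = cfg.ssp_conversion_scale.get(ssp, 1.0)
        for r in range(cfg.n_replicates):
            jitter = float(rng.normal(0.0, cfg.replicate_warming_jitter)) if r > 0 else 0.0
            warm = {
                arm: tuple(max(w + jitter, 0.0) for w in scen_base.warming[arm])
                for arm in ARMS
            }
            conv = {
                arm: tuple(min(c * scale, 1.0) for c in scen_base.conversion[arm])
                for arm in ARMS
            }
            sc = replace(scen_base, warming=warm, conversion=conv)
            scenario_sets[(ssp, f"rep{r}")] = generate_scenarios(
                base, sc, seed=cfg.seed + 100 + s_i
            )

    pool_names, pool_stack = predictor_stack(base)
    pool_idx = [pool_names.index(p) for p in cfg.predictor_pool]
    pool_flat = pool_stack[pool_idx].reshape(len(pool_idx), -1)
    allometry = default_allometry()
    y1, y2 = scen_base.horizon_years

    outcomes: list = []
    results = []
    current_areas = {}
    meta_rows = []
    land = base.land_mask

    for sp, occ in community:
        prepared = prepare_occurrences(occ, grid, min_records=cfg.min_records)
        out = SpeciesOutcome(
            species_id=sp.species_id,
            taxon_group=sp.taxon_group,
            region=f"region{sp.native_region}",
            m=prepared.m,
            pass_min_records=prepared.pass_min_records,
        )
        outcomes.append(out)
        if not prepared.pass_min_records:
            continue

        native = base.region_mask(sp.native_region)
        bg = sample_bias_background(
            density[sp.taxon_group], native, cfg.n_background,
            seed=cfg.seed + 1000 + int(sp.species_id[2:]),
        )
        bg_flat = bg.cells[:, 0] * grid.n_cols + bg.cells[:, 1]
        pres_flat = prepared.cells[:, 0] * grid.n_cols + prepared.cells[:, 1]
        bg_X = pool_flat[:, bg_flat].T
        pres_X = pool_flat[:, pres_flat].T

        cands = enumerate_candidate_sets(bg_X, cfg.predictor_pool)
        cand_sets = sorted(cands.sets)[: cfg.max_candidate_sets]

        beta_grid = tuple(
            np.arange(0.0, cfg.beta_grid_max + 1e-9, cfg.beta_grid_step)
        )
        model, diag = select_model(
            pres_X, bg_X, cfg.predictor_pool, cand_sets,
            beta_grid=beta_grid, background_weights=bg.counts.astype(float),
        )
        out.selected_set = diag.selected_set
        out.selected_beta = diag.selected_beta

        sel_idx = [cfg.predictor_pool.index(p) for p in diag.selected_set]
        cbi = evaluate_species(
            pres_X[:, sel_idx], bg_X[:, sel_idx], diag.selected_set,
            beta=model.beta, k=cfg.k_folds,
            seed=cfg.seed + 2000 + int(sp.species_id[2:]),
            background_weights=bg.counts.astype(float),
        )
        out.cbi_mean, out.cbi_ci_low, out.retained = cbi.mean, cbi.ci_low, cbi.retained
        if not cbi.retained:
            continue

        # 90%-sensitivity threshold on each fold's calibration presences,
        # then averaged; suitability = fold-mean prediction (as in CV averaging)
        from .evaluation import kfold_split
        from .maxent import predict_suitability

        folds = kfold_split(prepared.m, len(bg_X), k=cfg.k_folds,
                            seed=cfg.seed + 2000 + int(sp.species_id[2:]))
        fold_vals = [
            predict_suitability(mdl, pres_X[:, sel_idx][folds.presence_folds != i])
            for i, mdl in enumerate(cbi.fold_models)
        ]
        thr = sensitivity_threshold(fold_vals)
        out.threshold = thr.threshold

        def predict_fn(landscape, _models=cbi.fold_models):
            return np.mean(
                [predict_on_landscape(mdl, landscape) for mdl in _models], axis=0
            )

        disp1 = estimate_dispersal(sp.traits, sp.taxon_group, allometry, 0.0, y1)
        disp2 = estimate_dispersal(sp.traits, sp.taxon_group, allometry, y1, y2)
        out.d_g, out.generation = disp1.d_g, disp1.g
        out.D_h1, out.D_h2 = disp1.D, disp2.D

        meta_rows.append(
            {"species_id": sp.species_id, "taxon_group": sp.taxon_group,
             "region": f"region{sp.native_region}"}
        )
        for (ssp, rep), scen in scenario_sets.items():
            maps = project_species(
                predict_fn, thr.threshold, native, prepared.cells,
                (disp1.D, disp2.D), scen, species_id=sp.species_id,
            )
            h0 = maps["current"]
            current_areas[sp.species_id] = h0.area
            out.current_area = h0.area
            for arm in ARMS:
                for hz in HORIZONS:
                    res = decompose_change(
                        h0,
                        maps[(arm, hz, "LU")],
                        maps[(arm, hz, "CC")],
                        maps[(arm, hz, "LUCC")],
                        domain=native & land,
                    )
                    res.arm, res.horizon = arm, hz
                    res.ssp, res.replicate = ssp, rep
                    results.append(res)

    meta = pd.DataFrame(meta_rows, columns=["species_id", "taxon_group", "region"])
    if results:
        records = summarize_areas(results, meta, current_areas)
        records = records.sort_values(
            ["species_id", "ssp", "replicate", "arm", "horizon"]
        ).reset_index(drop=True)
    else:
        records = pd.DataFrame()

    glmm_lost = glmm_gained = None
    if len(records) and records["species_id"].nunique() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                glmm_lost = fit_area_glmm(records, "lost")
                glmm_gained = fit_area_glmm(records, "gained")
            except Exception as e:  # a degenerate demo run is not fatal
                warnings.warn(f"GLMM stage failed: {e}", stacklevel=2)

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_species": cfg.n_species,
        "n_retained": int(sum(o.retained for o in outcomes)),
        "package_version": _version(),
    }
    result = PipelineResult(cfg, outcomes, records, glmm_lost, glmm_gained, manifest)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _version() -> str:
    from . import __version__

    return __version__


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(outdir / "area_records.csv", index=False)
    pd.DataFrame([asdict(o) for o in result.outcomes]).to_csv(
        outdir / "species_outcomes.csv", index=False
    )
    for name, fit in (("glmm_lost", result.glmm_lost), ("glmm_gained", result.glmm_gained)):
        if fit is not None:
            fit.summary().to_csv(outdir / f"{name}.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
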