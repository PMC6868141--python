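"""Habitat maps, paleo-connectivity, dispersal, and PFH-CDD projection."""

import numpy as np
import pytest

import habishift as hs
from habishift.dispersal import DispersalRule, GenerationRule, fit_dispersal_rule
from habishift.habitat import HabitatMap, connectivity_filter, make_habitat_map, pfh_cdd
from habishift.species import TraitRecord


GRID = hs.GridSpec(15, 15, 50.0)


def hmap(mask, grid=GRID, **kw):
    return HabitatMap(mask=np.asarray(mask, dtype=bool), grid=grid, **kw)


class TestMakeHabitatMap:
    def test_threshold_zero_returns_native_land(self):
        suit = np.random.default_rng(0).uniform(0, 1, GRID.shape)
        native = np.zeros(GRID.shape, dtype=bool)
        native[:8] = True
        land = np.ones(GRID.shape, dtype=bool)
        hm = make_habitat_map(suit, 0.0, native, GRID, land_mask=land)
        assert np.array_equal(hm.mask, native)

    def test_threshold_above_max_gives_empty_map(self):
        suit = np.full(GRID.shape, 0.4)
        native = np.ones(GRID.shape, dtype=bool)
        hm = make_habitat_map(suit, 0.5, native, GRID)
        assert not hm.mask.any()
        assert hm.area == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_cellwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        suit = rng.uniform(0, 1, GRID.shape)
        native = rng.random(GRID.shape) > 0.3
        land = rng.random(GRID.shape) > 0.2
        if not native.any():
            native[0, 0] = True
        thr = 0.55
        hm = make_habitat_map(suit, thr, native, GRID, land_mask=land)
        for r in range(GRID.n_rows):
            for c in range(GRID.n_cols):
                want = suit[r, c] >= thr and native[r, c] and land[r, c]
                assert hm.mask[r, c] == want

    def test_empty_native_mask_rejected(self):
        with pytest.raises(ValueError):
            make_habitat_map(np.zeros(GRID.shape), 0.5,
                             np.zeros(GRID.shape, dtype=bool), GRID)

    def test_area_is_cell_area_weighted(self):
        mask = np.zeros(GRID.shape, dtype=bool)
        mask[0, :3] = True
        assert hmap(mask).area == pytest.approx(3 * 50.0**2)


class TestConnectivityFilter:
    def island_setup(self, channel_depth):
        """Two land blocks separated by a sea channel of given depth."""
        bathy = np.full((5, 9), 100.0)
        bathy[:, 4] = channel_depth
        habitat = np.ones((5, 9), dtype=bool)
        habitat[:, 4] = False
        occ = np.array([[2, 1]])  # occurrence on the left island only
        grid = hs.GridSpec(5, 9, 50.0)
        return HabitatMap(habitat, grid), bathy, occ

    def test_single_landmass_unchanged(self):
        hm, bathy, occ = self.island_setup(channel_depth=50.0)  # channel is land
        out = connectivity_filter(hm, bathy, occ)
        assert np.array_equal(out.mask, hm.mask)

    def test_deep_channel_removes_unoccupied_island(self):
        hm, bathy, occ = self.island_setup(channel_depth=-200.0)
        out = connectivity_filter(hm, bathy, occ)
        assert out.mask[:, :4].all()
        assert not out.mask[:, 5:].any()

    def test_shallow_channel_keeps_paleo_connected_island(self):
        # floor at -100 m is above the -130 m paleo coastline: one landmass
        hm, bathy, occ = self.island_setup(channel_depth=-100.0)
        out = connectivity_filter(hm, bathy, occ)
        assert np.array_equal(out.mask, hm.mask)

    def test_occurrences_off_all_landmasses_rejected(self):
        hm, bathy, _ = self.island_setup(channel_depth=-200.0)
        bathy[:] = -500.0
        with pytest.raises(ValueError):
            connectivity_filter(hm, bathy, np.array([[2, 1]]))


class TestDispersal:
    def test_total_distance_formula_on_trait_grid(self):
        for d_g in (0.5, 2.0, 7.5):
            for g in (1.0, 5.0, 20.0):
                for t1 in (30.0, 50.0):
                    est = hs.DispersalEstimate(d_g=d_g, g=g, t0=0.0, t1=t1)
                    assert est.D == pytest.approx(d_g * t1 / g)

    def test_generation_equal_to_span_gives_one_generation(self):
        est = hs.DispersalEstimate(d_g=3.0, g=50.0, t0=0.0, t1=50.0)
        assert est.D == pytest.approx(3.0)

    def test_log_linear_rule_matches_hand_computation(self):
        rule = DispersalRule(intercept=-1.0, log_mass_coef=0.5, carnivore_offset=0.3)
        for mass in (10.0, 100.0, 1000.0):
            for carn in (False, True):
                tr = TraitRecord(body_mass=mass, diet_carnivorous=carn,
                                 female_maturity=1.0, max_longevity=10.0)
                want = 10 ** (-1.0 + 0.5 * np.log10(mass) + 0.3 * carn)
                assert rule.predict_dg(tr) == pytest.approx(want)

    def test_estimate_dispersal_end_to_end(self):
        cfg = hs.default_allometry()
        tr = TraitRecord(body_mass=5000.0, diet_carnivorous=False,
                         female_maturity=2.0, max_longevity=12.0)
        est = hs.estimate_dispersal(tr, "mammal", cfg, 0.0, 40.0)
        assert est.g == pytest.approx(2.0 + 0.5 * 10.0)
        assert est.D == pytest.approx(est.d_g * 40.0 / est.g)

    def test_estimate_requires_forward_interval(self):
        cfg = hs.default_allometry()
        tr = TraitRecord(body_mass=100.0, female_maturity=1.0, max_longevity=5.0)
        with pytest.raises(ValueError):
            hs.estimate_dispersal(tr, "bird", cfg, 50.0, 50.0)

    def test_plant_rule_requires_growth_form(self):
        cfg = hs.default_allometry()
        tr = TraitRecord(body_mass=1.0, female_maturity=1.0, max_longevity=5.0)
        with pytest.raises(ValueError):
            hs.estimate_dispersal(tr, "vascular_plant", cfg, 0.0, 40.0)

    def test_ols_calibration_recovers_noiseless_coefficients(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        mass = 10 ** rng.uniform(0, 5, 40)
        carn = rng.random(40) < 0.5
        d = 10 ** (-0.8 + 0.42 * np.log10(mass) + 0.25 * carn)
        rule = fit_dispersal_rule(
            pd.DataFrame({"dispersal_km": d, "body_mass": mass,
                          "diet_carnivorous": carn}),
            use_mass=True, use_carnivore=True,
        )
        assert rule.intercept == pytest.approx(-0.8, abs=1e-8)
        assert rule.log_mass_coef == pytest.approx(0.42, abs=1e-8)
        assert rule.carnivore_offset == pytest.approx(0.25, abs=1e-8)


class TestPfhCdd:
    def test_zero_dispersal_intersects_previous(self):
        rng = np.random.default_rng(1)
        prev = hmap(rng.random(GRID.shape) > 0.5)
        fut = hmap(rng.random(GRID.shape) > 0.5)
        out = pfh_cdd(prev, fut, 0.0)
        assert np.array_equal(out.mask, prev.mask & fut.mask)

    def test_unbounded_dispersal_returns_future_suitable(self):
        rng = np.random.default_rng(2)
        prev = hmap(rng.random(GRID.shape) > 0.8)
        fut = hmap(rng.random(GRID.shape) > 0.5)
        diameter = GRID.cell_size * np.hypot(GRID.n_rows, GRID.n_cols)
        out = pfh_cdd(prev, fut, diameter)
        assert np.array_equal(out.mask, fut.mask)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_distance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prev = hmap(rng.random(GRID.shape) > 0.7)
        fut = hmap(rng.random(GRID.shape) > 0.5)
        D = 2.5 * GRID.cell_size
        out = pfh_cdd(prev, fut, D)
        prev_cells = np.argwhere(prev.mask)
        for r in range(GRID.n_rows):
            for c in range(GRID.n_cols):
                if not fut.mask[r, c]:
                    assert not out.mask[r, c]
                    continue
                if len(prev_cells) == 0:
                    reach = False
                else:
                    d2 = ((prev_cells - [r, c]) ** 2).sum(axis=1)
                    reach = np.sqrt(d2.min()) * GRID.cell_size <= D + 1e-9
                assert out.mask[r, c] == reach

    def test_area_monotone_in_dispersal_distance(self):
        rng = np.random.default_rng(3)
        prev = hmap(rng.random(GRID.shape) > 0.8)
        fut = hmap(rng.random(GRID.shape) > 0.4)
        areas = [pfh_cdd(prev, fut, d).area for d in np.linspace(0, 800, 17)]
        assert np.all(np.diff(areas) >= 0)

    def test_nesting_invariants(self):
        rng = np.random.default_rng(4)
        prev = hmap(rng.random(GRID.shape) > 0.7)
        fut = hmap(rng.random(GRID.shape) > 0.5)
        D = 130.0
        out = pfh_cdd(prev, fut, D)
        assert np.all(out.mask <= fut.mask)  # subset of future suitable
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(~prev.mask) * GRID.cell_size
        assert np.all(out.mask <= (dist <= D + 1e-9))

    def test_grid_mismatch_rejected(self):
        a = hmap(np.ones((15, 15), dtype=bool))
        b = HabitatMap(np.ones((10, 10), dtype=bool), hs.GridSpec(10, 10, 50.0))
        with pytest.raises(ValueError):
            pfh_cdd(a, b, 10.0)


@pytest.fixture(scope="module")
def setup():
    grid = hs.GridSpec(24, 24, 50.0)
    base = hs.generate_landscape(
        grid, hs.LandscapeConfig(sea_fraction=0.2, n_regions=1), seed=3
    )
    cfg = hs.SpeciesConfig(n_records=150, bias_strength=0.0)
    sp, occ = hs.generate_species(base, 1, cfg, seed=4)[0]
    suit_fn = lambda landscape: hs.true_suitability(sp, landscape)
    native = base.region_mask(sp.native_region)
    occ_cells = np.unique(occ.records, axis=0)
    return base, sp, suit_fn, native, occ_cells


class TestProjectSpecies:
    def test_identical_scenarios_leave_habitat_unchanged(self, setup):
        base, sp, suit_fn, native, occ_cells = setup
        cfg = hs.ScenarioConfig(
            warming={"mitigation": (0.0, 0.0), "baseline": (0.0, 0.0)},
            conversion={"mitigation": (0.0, 0.0), "baseline": (0.0, 0.0)},
        )
        scen = hs.generate_scenarios(base, cfg, seed=5)
        maps = hs.project_species(suit_fn, 0.3, native, occ_cells,
                                  (100.0, 100.0), scen)
        cur = maps["current"]
        for key, hm in maps.items():
            if key == "current":
                continue
            assert np.array_equal(hm.mask, cur.mask)

    def test_zero_dispersal_maps_only_shrink_across_horizons(self, setup):
        base, sp, suit_fn, native, occ_cells = setup
        scen = hs.generate_scenarios(base, hs.ScenarioConfig(), seed=6)
        maps = hs.project_species(suit_fn, 0.3, native, occ_cells,
                                  (0.0, 0.0), scen)
        cur = maps["current"]
        for arm in ("mitigation", "baseline"):
            for drv in ("LU", "CC", "LUCC"):
                h1 = maps[(arm, "h1", drv)]
                h2 = maps[(arm, "h2", drv)]
                assert np.all(h1.mask <= cur.mask)
                assert np.all(h2.mask <= h1.mask)

    def test_chained_projection_never_exceeds_unconstrained(self, setup):
        base, sp, suit_fn, native, occ_cells = setup
        scen = hs.generate_scenarios(base, hs.ScenarioConfig(), seed=6)
        d = (120.0, 90.0)
        maps = hs.project_species(suit_fn, 0.3, native, occ_cells, d, scen)
        for arm in ("mitigation", "baseline"):
            for drv in ("LU", "CC", "LUCC"):
                chained = maps[(arm, "h2", drv)]
                assert chained.area <= maps["current"].area + 1e6  # sanity
                # chained h2 is a subset of the unconstrained h2 suitable map
                land = scen.current.land_mask
                suit = suit_fn(scen.get(arm, "h2", drv))
                unconstrained = (suit >= 0.3) & native & land
                assert np.all(chained.mask <= unconstrained)
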