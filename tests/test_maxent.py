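"""Occurrence preparation, biased backgrounds, and the penalized log-linear SDM."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

import habishift as hs
from habishift.maxent import (
    DEFAULT_BETA_GRID,
    aicc,
    fit_maxent,
    predict_on_landscape,
    predict_suitability,
    prepare_occurrences,
    sample_bias_background,
    select_model,
)
from habishift.species import OccurrenceSet

from conftest import predictor_matrix_at


class TestPrepareOccurrences:
    grid = hs.GridSpec(10, 10, 50.0)

    def occ(self, records):
        records = np.asarray(records).reshape(-1, 2)
        return OccurrenceSet("spX", records, np.ones(len(records), dtype=bool))

    def test_many_records_in_one_cell_thin_to_one(self):
        p = prepare_occurrences(self.occ([(2, 3)] * 5), self.grid)
        assert p.m == 1
        assert p.cells.tolist() == [[2, 3]]

    def test_thirty_distinct_cells_pass_minimum(self):
        cells = [(i // 10, i % 10) for i in range(30)]
        p = prepare_occurrences(self.occ(cells), self.grid)
        assert p.m == 30 and p.pass_min_records

    def test_twentynine_distinct_cells_fail_minimum(self):
        cells = [(i // 10, i % 10) for i in range(29)]
        p = prepare_occurrences(self.occ(cells), self.grid)
        assert p.m == 29 and not p.pass_min_records

    def test_empty_input_fails_gracefully(self):
        p = prepare_occurrences(self.occ(np.empty((0, 2), dtype=int)), self.grid)
        assert p.m == 0 and not p.pass_min_records

    def test_off_grid_record_rejected(self):
        with pytest.raises(ValueError):
            prepare_occurrences(self.occ([(11, 0)]), self.grid)


class TestBiasBackground:
    def test_uniform_density_gives_uniform_frequencies(self):
        mask = np.ones((10, 10), dtype=bool)
        bg = sample_bias_background(np.ones((10, 10)), mask, 100_000, seed=1)
        counts = np.zeros(100)
        counts[bg.cells[:, 0] * 10 + bg.cells[:, 1]] = bg.counts
        stat, p = chisquare(counts)
        assert p > 0.001

    def test_single_positive_cell_takes_all_draws(self):
        dens = np.zeros((5, 5))
        dens[2, 2] = 3.0
        bg = sample_bias_background(dens, np.ones((5, 5), dtype=bool), 500, seed=0)
        assert bg.cells.tolist() == [[2, 2]]
        assert bg.counts[0] == 500

    def test_mask_excludes_region(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[:3] = True
        bg = sample_bias_background(np.ones((6, 6)), mask, 2000, seed=2)
        assert bg.cells[:, 0].max() < 3

    def test_all_zero_density_rejected(self):
        with pytest.raises(ValueError):
            sample_bias_background(np.zeros((4, 4)), np.ones((4, 4), dtype=bool), 10)


class TestFitMaxent:
    def test_constant_feature_gives_uniform_model_with_zero_weight(self):
        pres = np.full((5, 1), 2.0)
        bg = np.full((20, 1), 2.0)
        m = fit_maxent(pres, bg, beta=0.0)
        assert np.all(m.lambdas == 0.0)
        assert m.k == 0

    def test_huge_beta_shrinks_all_weights_to_zero(self):
        rng = np.random.default_rng(0)
        m = fit_maxent(rng.uniform(1, 2, (30, 2)), rng.uniform(0, 1, (100, 2)),
                       beta=1e6)
        assert np.all(m.lambdas == 0.0)
        suit = predict_suitability(m, rng.uniform(0, 2, (50, 2)))
        assert np.allclose(suit, suit[0])

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            fit_maxent(np.ones((3, 1)), np.ones((5, 1)), beta=-0.5)

    def test_single_linear_feature_matches_grid_search_oracle(self):
        """Unpenalized 1-D fit against a brute-force scan of the objective."""
        rng = np.random.default_rng(1)
        bg = rng.uniform(0, 1, (10, 1))
        pres = rng.uniform(0.3, 0.9, (6, 1))
        m = fit_maxent(pres, bg, beta=0.0, quadratic=False)

        spec = m.spec
        F_pres = spec.transform(pres)
        bg_all = np.vstack([bg, pres])  # presences join the background
        F_bg = spec.transform(bg_all)
        w = np.full(len(bg_all), 1.0 / len(bg_all))

        def objective(lam):
            eta = F_bg[:, 0] * lam
            z = np.log(np.sum(w * np.exp(eta)))
            return -F_pres[:, 0].mean() * lam + z

        grid = np.linspace(-20, 20, 400_001)
        vals = np.array([objective(l) for l in grid[:: 1]])
        best = grid[vals.argmin()]
        assert m.lambdas[0] == pytest.approx(best, abs=1e-3)

    def test_objective_never_increases_across_iterations(self):
        rng = np.random.default_rng(2)
        trace: list = []
        fit_maxent(rng.normal(1, 0.5, (40, 3)), rng.normal(0, 1, (300, 3)),
                   beta=0.5, objective_trace=trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-12)

    def test_raw_outputs_normalize_over_background(self):
        rng = np.random.default_rng(3)
        pres = rng.normal(1, 0.5, (25, 2))
        bg = rng.normal(0, 1, (200, 2))
        m = fit_maxent(pres, bg, beta=0.0)
        bg_all = np.vstack([bg, pres])
        w = np.full(len(bg_all), 1.0 / len(bg_all))
        eta = m.spec.transform(bg_all) @ m.lambdas + np.log(w)
        assert np.exp(eta - m.log_z).sum() == pytest.approx(1.0, abs=1e-9)


class TestAicc:
    def _model_with(self, k, m, ll):
        rng = np.random.default_rng(0)
        mdl = fit_maxent(rng.uniform(1, 2, (m, k)), rng.uniform(0, 1, (50, k)))
        return mdl

    def test_formula_value(self):
        mdl = self._model_with(2, 30, None)
        mdl.lambdas = np.array([1.0, 0.0, 2.0, 0.0])  # k = 2
        got = aicc(mdl, loglik=-50.0, m=30)
        assert got == pytest.approx(104 + 12 / 27)

    def test_boundary_m_equals_k_plus_one(self):
        mdl = self._model_with(2, 5, None)
        mdl.lambdas = np.array([1.0, 1.0, 1.0, 1.0])  # k = 4
        assert aicc(mdl, loglik=-10.0, m=5) == np.inf

    def test_nonfinite_loglik_reported_infinite(self):
        mdl = self._model_with(1, 30, None)
        assert aicc(mdl, loglik=-np.inf, m=30) == np.inf

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(4)
        mdl = fit_maxent(rng.normal(1, 0.3, (40, 2)), rng.normal(0, 1, (150, 2)),
                         beta=0.5)
        k = int(np.sum(np.abs(mdl.lambdas) > 1e-8))
        want = 2 * k - 2 * mdl.loglik + 2 * k * (k + 1) / (40 - k - 1)
        assert mdl.aicc == pytest.approx(want)


class TestSelectModel:
    def test_default_beta_grid_has_31_values_and_31_stage2_fits(self):
        assert len(DEFAULT_BETA_GRID) == 31
        assert DEFAULT_BETA_GRID[0] == 0.0
        assert DEFAULT_BETA_GRID[-1] == 15.0
        rng = np.random.default_rng(5)
        pres = rng.normal(1, 0.5, (40, 2))
        bg = rng.normal(0, 1, (200, 2))
        _, diag = select_model(pres, bg, ("a", "b"), [("a", "b")])
        assert diag.n_stage2_fits == 31

    def test_single_candidate_trivially_selected(self):
        rng = np.random.default_rng(6)
        _, diag = select_model(
            rng.normal(1, 0.5, (30, 1)), rng.normal(0, 1, (100, 1)),
            ("x",), [("x",)], beta_grid=(0.0, 1.0),
        )
        assert diag.selected_set == ("x",)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generating_predictor_set_beats_decoy(self, landscape40, seed):
        cfg = hs.SpeciesConfig(n_records=260, bias_strength=0.0)
        sp, occ = hs.generate_species(landscape40, 1, cfg, seed=seed)[0]
        prep = prepare_occurrences(occ, landscape40.grid)
        native = landscape40.region_mask(sp.native_region)
        bg = sample_bias_background(np.ones(landscape40.grid.shape), native,
                                    2000, seed=100 + seed)
        decoys = [p for p in ("bio2", "bio15", "lu_settled")
                  if p not in sp.predictor_names][:2]
        pool = tuple(sp.predictor_names) + tuple(decoys)
        pres_X = predictor_matrix_at(landscape40, prep.cells, pool)
        bg_X = predictor_matrix_at(landscape40, bg.cells, pool)
        mdl, diag = select_model(
            pres_X, bg_X, pool, [tuple(sp.predictor_names), tuple(decoys)],
            background_weights=bg.counts.astype(float),
        )
        assert diag.selected_set == tuple(sp.predictor_names)


class TestPredict:
    def test_uniform_model_constant_raster(self, landscape40):
        rng = np.random.default_rng(7)
        m = fit_maxent(rng.uniform(1, 2, (20, 2)), rng.uniform(0, 1, (80, 2)),
                       beta=1e6)
        from habishift.maxent import FeatureSpec

        m.spec = FeatureSpec(("bio1", "bio12"), m.spec.lower, m.spec.upper)
        suit = predict_on_landscape(m, landscape40)
        assert np.allclose(suit, suit.flat[0])

    def test_suitability_ranks_follow_linear_predictor(self):
        rng = np.random.default_rng(8)
        m = fit_maxent(rng.normal(1, 0.5, (30, 2)), rng.normal(0, 1, (120, 2)))
        X = rng.normal(0, 1, (500, 2))
        eta = m.linear_predictor(X)
        suit = predict_suitability(m, X)
        rho = spearmanr(eta, suit).statistic
        assert rho == pytest.approx(1.0)

    def test_missing_predictor_layer_rejected(self):
        rng = np.random.default_rng(9)
        m = fit_maxent(rng.normal(1, 0.5, (10, 2)), rng.normal(0, 1, (50, 2)))
        with pytest.raises(ValueError):
            predict_suitability(m, rng.normal(0, 1, (5, 3)))


class TestRecovery:
    def test_parameter_recovery_on_fixed_seed(self, landscape40):
        """Spearman(true, predicted) over land cells for a well-specified
        species at m ~ 200, n_bg = 2000."""
        cfg = hs.SpeciesConfig(n_records=260, bias_strength=0.0)
        sp, occ = hs.generate_species(landscape40, 1, cfg, seed=1)[0]
        prep = prepare_occurrences(occ, landscape40.grid)
        native = landscape40.region_mask(sp.native_region)
        bg = sample_bias_background(np.ones(landscape40.grid.shape), native,
                                    2000, seed=11)
        pool = tuple(sp.predictor_names)
        pres_X = predictor_matrix_at(landscape40, prep.cells, pool)
        bg_X = predictor_matrix_at(landscape40, bg.cells, pool)
        mdl, _ = select_model(pres_X, bg_X, pool, [pool],
                              background_weights=bg.counts.astype(float))
        suit = predict_on_landscape(mdl, landscape40)
        truth = hs.true_suitability(sp, landscape40)
        land = landscape40.land_mask
        assert spearmanr(truth[land], suit[land]).statistic >= 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_shared_bias_cancels_with_biased_background(self, seed):
        """Strong sampling bias shared by presences and background leaves
        rank recovery intact; a uniform background does worse."""
        grid = hs.GridSpec(40, 40, 50.0)
        base = hs.generate_landscape(
            grid, hs.LandscapeConfig(sea_fraction=0.2, n_regions=1), seed=11
        )
        cfg = hs.SpeciesConfig(n_records=250, bias_strength=2.0)
        sp, occ = hs.generate_species(base, 1, cfg, seed=seed)[0]
        prep = prepare_occurrences(occ, grid)
        native = base.region_mask(sp.native_region)
        pool = tuple(sp.predictor_names)
        pres_X = predictor_matrix_at(base, prep.cells, pool)
        truth = hs.true_suitability(sp, base)
        land = base.land_mask
        rhos = {}
        for kind, dens in (("biased", occ.bias_surface),
                           ("uniform", np.ones(grid.shape))):
            bg = sample_bias_background(dens, native, 2000, seed=100 + seed)
            bg_X = predictor_matrix_at(base, bg.cells, pool)
            mdl = fit_maxent(pres_X, bg_X, beta=0.0,
                             background_weights=bg.counts.astype(float))
            from habishift.maxent import FeatureSpec

            mdl.spec = FeatureSpec(pool, mdl.spec.lower, mdl.spec.upper)
            suit = predict_on_landscape(mdl, base)
            rhos[kind] = spearmanr(truth[land], suit[land]).statistic
        assert rhos["biased"] >= 0.8
        assert rhos["biased"] > rhos["uniform"]


def test_model_json_roundtrip():
    rng = np.random.default_rng(10)
    m = fit_maxent(rng.normal(1, 0.5, (20, 2)), rng.normal(0, 1, (80, 2)), beta=0.5)
    m2 = hs.MaxEntModel.from_json(m.to_json())
    X = rng.normal(0, 1, (40, 2))
    np.testing.assert_allclose(predict_suitability(m, X), predict_suitability(m2, X))
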