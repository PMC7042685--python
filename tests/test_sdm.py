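import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from shapely.geometry import Point

from landgen import (
    EnvStack, GeographicNullModel, Grid, LandscapeSimConfig, OccurrenceSet,
    Raster, auc, calibrated_auc, consensus, ensemble_search, fit_base_model,
    register_model, retain_models, sample_background, simulate_landscape,
    soil_depth_mean, threshold_limited_map, threshold_max_sens_spec,
    vif_prune,
)
from landgen.sdm import (
    SdmError, background_region, enumerate_anchored_subsets, mann_whitney_u,
)


@pytest.fixture(scope="module")
def landscape():
    return simulate_landscape(LandscapeSimConfig(
        seed=3, nrows=80, ncols=80, n_layers=4, n_presences=120))


@pytest.fixture(scope="module")
def fitted(landscape):
    stack, occ, truth = landscape
    bg = sample_background(occ, stack.grid, max_n=800, seed=1)
    env = fit_base_model("envelope", occ, bg, stack, seed=0)
    logi = fit_base_model("logistic", occ, bg, stack, seed=0)
    return stack, occ, bg, env, logi


class TestBackground:
    def test_unit_square_buffered_hull(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        region = background_region(OccurrenceSet(points=pts))
        # buffer width = 0.1 * diagonal
        w = 0.1 * np.sqrt(2)
        assert region.contains(Point(-w + 1e-6, 0.5))
        assert not region.contains(Point(-w - 1e-2, 0.5))

    def test_cell_uniqueness_binds(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        grid = Grid(west=-0.5, north=1.5, cell_size=0.1, nrows=20, ncols=20)
        bg = sample_background(OccurrenceSet(points=pts), grid,
                               max_n=10_000, seed=0)
        # cannot exceed number of cells in the region; all points distinct cells
        rows, cols = grid.index_of(bg.points[:, 0], bg.points[:, 1])
        assert len(set(zip(rows, cols))) == len(bg)
        assert len(bg) < 400

    def test_all_samples_inside_region_brute_force(self, landscape):
        stack, occ, _ = landscape
        bg = sample_background(occ, stack.grid, max_n=500, seed=2)
        region = background_region(occ)
        violations = sum(
            0 if region.buffer(1e-9).contains(Point(x, y)) else 1
            for x, y in bg.points)
        assert violations == 0

    def test_presence_cells_excluded(self, landscape):
        stack, occ, _ = landscape
        bg = sample_background(occ, stack.grid, max_n=2000, seed=3)
        pr = set(zip(*stack.grid.index_of(occ.points[:, 0], occ.points[:, 1])))
        br = set(zip(*stack.grid.index_of(bg.points[:, 0], bg.points[:, 1])))
        assert not (pr & br)

    def test_too_few_presences(self):
        with pytest.raises(SdmError):
            background_region(OccurrenceSet(points=np.array([[0, 0], [1, 1.0]])))


class TestVif:
    def test_duplicate_layer_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        samples = np.column_stack([x, x, y])
        kept = vif_prune(None, samples=samples, names=["a", "a2", "b"])
        assert kept == ["a", "b"]

    def test_orthogonal_layers_all_kept(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(size=(500, 4))
        kept = vif_prune(None, samples=samples,
                         names=["a", "b", "c", "d"])
        assert kept == ["a", "b", "c", "d"]

    def test_against_exhaustive_oracle(self):
        """On small correlated instances the iterative prune must end with
        all VIF < 5; compare its result size with the best achievable."""
        from itertools import combinations
        rng = np.random.default_rng(2)
        z = rng.normal(size=(300, 2))
        noise = rng.normal(size=(300, 5))
        X = np.column_stack([
            z[:, 0],
            z[:, 0] * 0.98 + 0.1 * noise[:, 0],
            z[:, 1],
            z[:, 1] * 0.7 + 0.7 * noise[:, 1],
            noise[:, 2],
        ])
        names = list("abcde")
        kept = vif_prune(None, samples=X, names=names)

        def all_vif_ok(cols):
            sub = X[:, cols]
            if sub.shape[1] == 1:
                return True
            from landgen.sdm import _vif
            return all(_vif(sub, j) < 5 for j in range(sub.shape[1]))

        kept_idx = [names.index(n) for n in kept]
        assert all_vif_ok(kept_idx)
        best = max((c for r in range(1, 6)
                    for c in combinations(range(5), r) if all_vif_ok(c)),
                   key=len)
        assert len(kept) == len(best)


class TestSoilDepthMean:
    def test_constant_layers(self):
        v = [np.full((2, 2), 3.0)] * 5
        np.testing.assert_allclose(soil_depth_mean(v), 3.0)

    def test_hand_computed_weights(self):
        layers = [np.full((1, 1), x) for x in (10, 10, 10, 20, 20)]
        assert soil_depth_mean(layers)[0, 0] == pytest.approx(17.0)

    def test_weights_sum_to_one(self):
        from landgen.sdm import SOIL_DEPTH_WEIGHTS
        assert sum(SOIL_DEPTH_WEIGHTS) == 1.0

    def test_missing_depth_propagates(self):
        layers = [np.full((1, 2), 1.0) for _ in range(5)]
        layers[2][0, 1] = np.nan
        out = soil_depth_mean(layers)
        assert out[0, 0] == 1.0 and np.isnan(out[0, 1])


class TestBaseModels:
    def test_envelope_suitability_one_at_median(self, fitted):
        stack, occ, bg, env, _ = fitted
        Xp = stack.features_at(occ.points[:, 0], occ.points[:, 1])
        med = np.median(Xp, axis=0, keepdims=True)
        assert env.predict(med)[0] == 1.0

    def test_logistic_separable_training_auc_one(self):
        Xp = np.column_stack([np.linspace(2, 3, 20)])
        Xb = np.column_stack([np.linspace(-3, -2, 20)])
        from landgen.sdm import RegularizedLogisticModel
        m = RegularizedLogisticModel(seed=0).fit(Xp, Xb)
        assert auc(m.predict(Xp), m.predict(Xb)) == 1.0

    def test_logistic_recovers_coefficient_signs(self, landscape):
        stack, occ, truth = landscape
        bg = sample_background(occ, stack.grid, max_n=800, seed=5)
        m = fit_base_model("logistic", occ, bg, stack, seed=0)
        coef = m.coef_
        true = truth.coefficients
        nonzero = np.abs(true) > 1e-9
        assert (np.sign(coef[nonzero]) == np.sign(true[nonzero])).all()
        # rank of magnitudes matches
        assert (np.argsort(-np.abs(coef[nonzero]))
                == np.argsort(-np.abs(true[nonzero]))).all()

    def test_unknown_model_and_registry(self, fitted):
        stack, occ, bg, *_ = fitted
        with pytest.raises(SdmError, match="unknown model"):
            fit_base_model("maxent", occ, bg, stack)

        class Constant:
            name = "constant"
            def fit(self, Xp, Xb):
                return self
            def predict(self, X):
                return np.full(len(X), 0.5)

        register_model("constant", Constant)
        m = fit_base_model("constant", occ, bg, stack)
        assert np.all(m.predict(np.zeros((3, 4))) == 0.5)


class TestGeographicNull:
    def test_score_extremes(self, landscape):
        stack, occ, _ = landscape
        null = GeographicNullModel(occ.points, stack.grid)
        assert null.score_points(occ.points[:1])[0] == 1.0
        lon, lat = stack.grid.centers()
        cells = np.column_stack([lon.ravel(), lat.ravel()])
        scores = null.score_points(cells)
        assert scores.min() == pytest.approx(0.0, abs=1e-9)

    def test_null_auc_reveals_spatial_sorting_bias(self, landscape):
        """A clustered test set near training presences is separable from
        random background by geography alone."""
        stack, occ, _ = landscape
        rng = np.random.default_rng(0)
        train = occ.points[:80]
        test = occ.points[80:]
        null = GeographicNullModel(train, stack.grid)
        lon, lat = stack.grid.centers()
        cells = np.column_stack([lon.ravel(), lat.ravel()])
        far = cells[rng.choice(len(cells), 200, replace=False)]
        assert auc(null.score_points(test), null.score_points(far)) > 0.6


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pos = np.round(rng.uniform(0, 1, 23), 1)
            neg = np.round(rng.uniform(0, 1, 31), 1)
            brute = np.mean([
                1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos for n in neg])
            assert auc(pos, neg) == pytest.approx(brute, abs=1e-12)


class TestCalibratedAuc:
    def test_null_against_itself_exactly_half(self, fitted):
        stack, occ, bg, *_ = fitted
        null = GeographicNullModel(occ.points, stack.grid)
        res = calibrated_auc(null, occ, bg, stack, k_folds=4, seed=0)
        assert res.cauc == [0.5] * 4

    def test_informative_model_beats_half(self, fitted):
        stack, occ, bg, _, logi = fitted
        res = calibrated_auc(logi, occ, bg, stack, k_folds=4, seed=0)
        assert np.mean(res.cauc) > 0.55

    def test_insufficient_background_skips_folds(self, fitted):
        stack, occ, _, _, logi = fitted
        tiny_bg = OccurrenceSet(points=np.array([[-77.9, 7.9]]))
        res = calibrated_auc(logi, occ, tiny_bg, stack, k_folds=4, seed=0)
        assert res.cauc == []


class TestRetention:
    def test_clear_winner_retained(self):
        model = {"m": np.full(20, 0.9)}
        kept = retain_models(model, np.full(20, 0.5))
        assert kept == ["m"]

    def test_equal_to_null_not_retained(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.4, 0.6, 20)
        kept = retain_models({"m": vals}, vals.copy())
        assert kept == []

    def test_u_statistic_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = np.round(rng.uniform(0, 1, 15), 1)
        y = np.round(rng.uniform(0, 1, 12), 1)
        brute = sum(1.0 if a > b else 0.5 if a == b else 0.0
                    for a in x for b in y)
        assert mann_whitney_u(x, y) == pytest.approx(brute)
        assert mannwhitneyu(x, y, alternative="greater").statistic == \
            pytest.approx(brute)


class TestEnsemble:
    def test_enumeration_counts(self):
        names11 = [f"m{i}" for i in range(11)]
        assert len(enumerate_anchored_subsets(names11, "m0")) == 1024
        names14 = [f"m{i}" for i in range(14)]
        assert len(enumerate_anchored_subsets(names14, "m0")) == 8192

    def test_anchor_must_be_retained(self):
        with pytest.raises(SdmError):
            enumerate_anchored_subsets(["a", "b"], "z")

    def test_combinatorial_guard(self):
        names = [f"m{i}" for i in range(17)]
        with pytest.raises(SdmError, match="pre-filter"):
            enumerate_anchored_subsets(names, "m0")

    def test_single_model_ensemble(self, fitted):
        stack, occ, bg, _, logi = fitted
        best, table = ensemble_search({"logistic": logi}, {"logistic": 0.8},
                                      "logistic", occ, bg, stack, seed=0)
        assert best.members == ["logistic"]
        np.testing.assert_allclose(best.weights, [1.0])

    def test_convex_combination_and_anchor_bound(self, fitted):
        stack, occ, bg, env, logi = fitted
        models = {"envelope": env, "logistic": logi}
        best, table = ensemble_search(models, {"envelope": 0.7, "logistic": 0.8},
                                      "logistic", occ, bg, stack, seed=0)
        assert len(table) == 2
        # selected ensemble at least as good as anchor alone on the search CV
        assert best.cauc >= table[("logistic",)] - 1e-12
        # convexity of predictions
        X = stack.features_at(bg.points[:50, 0], bg.points[:50, 1])
        preds = np.column_stack([m.predict(X) for m in
                                 [models[n] for n in best.members]])
        ens = best.predict(X)
        assert (ens <= preds.max(axis=1) + 1e-12).all()
        assert (ens >= preds.min(axis=1) - 1e-12).all()


class TestThresholdConsensus:
    def test_tie_breaks_to_lower_threshold(self):
        t = threshold_max_sens_spec([0.8, 0.6], [0.4, 0.2])
        assert t == 0.6
        # brute force over all candidate scores agrees
        cands = [0.2, 0.4, 0.6, 0.8]
        def ss(th):
            sens = np.mean(np.array([0.8, 0.6]) >= th)
            spec = np.mean(np.array([0.4, 0.2]) < th)
            return sens + spec
        best = max(cands, key=lambda c: (ss(c), -c))
        assert t == best

    def test_degenerate_scores(self):
        assert threshold_max_sens_spec([0.5, 0.5], [0.5]) == 0.5

    def test_single_scenario_consensus(self):
        grid = Grid(west=0, north=2, cell_size=1.0, nrows=2, ncols=2)
        m = Raster(grid, np.array([[1.0, 0.0], [0.0, 1.0]]))
        c = consensus([m])
        np.testing.assert_allclose(c.optimistic.values, c.pessimistic.values)

    def test_31_scenarios_majority_counting(self):
        rng = np.random.default_rng(9)
        grid = Grid(west=0, north=10, cell_size=1.0, nrows=10, ncols=10)
        maps = [Raster(grid, rng.integers(0, 2, (10, 10)).astype(float))
                for _ in range(31)]
        c = consensus(maps)
        counts = np.sum([m.values for m in maps], axis=0)
        np.testing.assert_allclose(c.pessimistic.values, counts >= 16)
        np.testing.assert_allclose(c.optimistic.values, counts >= 1)
        # optimistic is a superset of pessimistic
        assert np.all(c.optimistic.values >= c.pessimistic.values)

    def test_threshold_limited_map_masks_nodata(self):
        grid = Grid(west=0, north=1, cell_size=1.0, nrows=1, ncols=3)
        r = Raster(grid, np.array([[0.9, 0.1, np.nan]]))
        b = threshold_limited_map(r, 0.5)
        assert b.values[0, 0] == 1.0 and b.values[0, 1] == 0.0
        assert np.isnan(b.values[0, 2])
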