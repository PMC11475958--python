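import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from nirmoist import GAConfig, GAPLSSelector, ga_select, pls_fitness, wavelength_importance
from conftest import planted_signal

SMALL_GA = GAConfig(
    population_size=24, n_generations=10, min_selected=2,
    pls_components=2, cv_folds=3, seed=0,
)


class TestPLSFitness:
    def test_exact_linear_map_scores_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (60, 10))
        y = 2.0 * x[:, 3] - 1.5 * x[:, 7]
        mask = np.zeros(10, dtype=bool)
        mask[[3, 7]] = True
        fit = pls_fitness(mask, x, y, SMALL_GA)
        assert fit > -1e-8

    def test_full_mask_matches_independent_cv_recomputation(self):
        x, y = planted_signal(1, n=80, p=20, informative=(3, 13))
        config = SMALL_GA
        fit = pls_fitness(np.ones(20, dtype=bool), x, y, config)
        # independent oracle: explicit KFold + PLS loop
        kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
        errors = []
        for tr, te in kf.split(x):
            pls = PLSRegression(n_components=config.pls_components, scale=False)
            pls.fit(x[tr], y[tr])
            errors.append((pls.predict(x[te]).ravel() - y[te]) ** 2)
        assert fit == pytest.approx(-np.mean(np.concatenate(errors)), rel=1e-12)

    def test_noise_channels_score_below_informative_ones(self):
        x, y = planted_signal(2, n=100, p=30, informative=(4, 20))
        informative = np.zeros(30, dtype=bool)
        informative[[4, 20]] = True
        noise = np.zeros(30, dtype=bool)
        noise[[1, 2, 9]] = True
        assert pls_fitness(informative, x, y, SMALL_GA) > pls_fitness(noise, x, y, SMALL_GA)

    def test_infeasible_mask_returns_sentinel_not_exception(self):
        x, y = planted_signal(3, n=40, p=10, informative=(2, 7))
        assert pls_fitness(np.zeros(10, dtype=bool), x, y, SMALL_GA) == -np.inf


class TestGASelect:
    def test_recovers_planted_channels(self):
        x, y = planted_signal(0)
        result = ga_select(x, y, SMALL_GA)
        assert {10, 40} <= set(result.selected_channels.tolist())

    def test_best_fitness_history_non_decreasing_under_elitism(self):
        x, y = planted_signal(4, n=60, p=20, informative=(3, 13))
        result = ga_select(x, y, SMALL_GA)
        assert result.best_fitness_per_generation.size == SMALL_GA.n_generations
        assert np.all(np.diff(result.best_fitness_per_generation) >= 0)

    def test_selected_subset_never_worse_than_full_mask(self):
        x, y = planted_signal(5, n=60, p=20, informative=(3, 13))
        result = ga_select(x, y, SMALL_GA)
        full = pls_fitness(np.ones(20, dtype=bool), x, y, SMALL_GA)
        assert result.best_fitness >= full

    def test_fixed_seed_reproduces_result(self):
        x, y = planted_signal(6, n=50, p=15, informative=(3, 11))
        a = ga_select(x, y, SMALL_GA)
        b = ga_select(x, y, SMALL_GA)
        assert np.array_equal(a.selected_channels, b.selected_channels)
        assert np.array_equal(a.best_fitness_per_generation, b.best_fitness_per_generation)

    def test_wavelengths_attached_when_grid_given(self):
        x, y = planted_signal(7, n=40, p=12, informative=(2, 8))
        grid = np.linspace(900, 1010, 12)
        result = ga_select(x, y, SMALL_GA, wavelengths=grid)
        np.testing.assert_array_equal(
            result.selected_wavelengths_nm, grid[result.selected_channels]
        )


class TestWavelengthImportance:
    def test_informative_channel_dominates(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 1, 200)
        x = np.column_stack([a, b])
        coef = wavelength_importance(x, 3.0 * a, pls_components=2)
        assert abs(coef[0]) / max(abs(coef[1]), 1e-300) > 100

    def test_constant_response_gives_zero_coefficients(self):
        x = np.random.default_rng(9).normal(0, 1, (30, 4))
        np.testing.assert_array_equal(wavelength_importance(x, np.full(30, 2.0), 2), 0.0)

    def test_duplicated_channel_splits_coefficient_but_predictions_unchanged(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0, 1, 100)
        y = a + 0.2 * b
        coef2 = wavelength_importance(np.column_stack([a, b]), y, 2)
        coef3 = wavelength_importance(np.column_stack([a, a, b]), y, 2)
        assert coef3[0] + coef3[1] == pytest.approx(coef2[0], rel=1e-6)
        # fitted values are invariant to duplicating a predictor
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        p2 = PLSRegression(2, scale=False).fit(np.column_stack([za, zb]), y)
        p3 = PLSRegression(2, scale=False).fit(np.column_stack([za, za, zb]), y)
        np.testing.assert_allclose(
            p2.predict(np.column_stack([za, zb])).ravel(),
            p3.predict(np.column_stack([za, za, zb])).ravel(),
            atol=1e-8,
        )

    def test_excess_components_reduced_with_warning(self):
        x = np.random.default_rng(11).normal(0, 1, (10, 3))
        y = x[:, 0]
        with pytest.warns(UserWarning, match="reduced"):
            wavelength_importance(x, y, pls_components=8)


class TestSelectorEstimator:
    def test_sklearn_selector_api(self):
        x, y = planted_signal(12, n=60, p=20, informative=(3, 13))
        sel = GAPLSSelector(population_size=16, n_generations=5, min_selected=2,
                            pls_components=2, cv_folds=3, random_state=0)
        xt = sel.fit_transform(x, y)
        support = sel.get_support()
        assert xt.shape == (60, support.sum())
        assert support.dtype == bool
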