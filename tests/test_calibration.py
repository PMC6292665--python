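import math

import numpy as np
import pytest

import standcount as sc
from standcount.calibration import (
    SingularFitError,
    UndefinedCorrelationError,
    calibrate_models,
    fit_density_model,
    grid_search,
    grid_to_dataframe,
    loocv,
    loocv_predictions,
    pearson_r,
)
from standcount.synthetic_scene import BROADLEAF, CONIFEROUS, UNCLASSIFIED

from conftest import make_observations


def oracle_pearson(x, y):
    """Independent direct-summation covariance / (sx * sy) oracle."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def oracle_ols(x, y, degree):
    """Normal-equations fit by explicit linear solve."""
    X = np.vander(np.asarray(x, float), degree + 1, increasing=True)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


class TestPearsonR:
    def test_perfect_positive(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_r(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 5.0]
        r, _ = pearson_r(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            r, _ = pearson_r(x, y)
            assert r == pytest.approx(oracle_pearson(list(x), list(y)), abs=1e-12)

    def test_p_value_matches_t_distribution(self, rng):
        from scipy import stats
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, p = pearson_r(x, y)
        t = r * math.sqrt(28 / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-12)
        # cross-check against scipy's own implementation
        assert p == pytest.approx(stats.pearsonr(x, y).pvalue, rel=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])

    def test_p_monotone_in_r_at_fixed_n(self):
        # stronger |r| at the same n must give a smaller p
        n = 15
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        noise = rng.normal(size=n)
        pairs = []
        for lam in (0.2, 0.5, 1.0, 2.0, 5.0):
            r, p = pearson_r(x, lam * x + noise)
            pairs.append((abs(r), p))
        pairs.sort()
        ps = [p for _, p in pairs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _tables_for(combos, n_prime_by_combo, nt, strata):
    tables = {}
    for combo in combos:
        tables[combo] = [
            sc.PlotObservation(f"P{i:03d}", strata[i], int(nt[i]),
                               int(n_prime_by_combo[combo][i]))
            for i in range(len(nt))
        ]
    return tables


class TestGridSearch:
    def test_exact_combination_selected(self, rng):
        nt = rng.integers(4, 60, size=12)
        strata = [UNCLASSIFIED] * 12
        combos = [("PAN", 3, 0.1), ("PAN", 3, 0.3), ("PAN", 5, 0.1)]
        n_prime = {
            ("PAN", 3, 0.1): nt + rng.integers(-3, 4, size=12),
            ("PAN", 3, 0.3): nt,  # exact
            ("PAN", 5, 0.1): rng.integers(0, 60, size=12),
        }
        tables = _tables_for(combos, n_prime, nt, strata)
        cells, best = grid_search(tables, strata=(UNCLASSIFIED,))
        chosen = best[UNCLASSIFIED]
        assert (chosen.band, chosen.window_size, chosen.ndvi_threshold) == ("PAN", 3, 0.3)
        assert chosen.r == pytest.approx(1.0)
        assert chosen.significant

    def test_constant_counts_give_undefined_cells_and_none_best(self, rng):
        nt = rng.integers(4, 60, size=10)
        combos = [("PAN", 3, 0.1), ("NIR", 3, 0.1)]
        n_prime = {c: np.full(10, 7) for c in combos}
        tables = _tables_for(combos, n_prime, nt, [UNCLASSIFIED] * 10)
        cells, best = grid_search(tables, strata=(UNCLASSIFIED,))
        assert all(math.isnan(c.r) for c in cells)
        assert best[UNCLASSIFIED] is None

    def test_small_stratum_skipped_with_warning(self, rng):
        nt = rng.integers(4, 60, size=5)
        strata = [CONIFEROUS] * 2 + [BROADLEAF] * 3
        combos = [("PAN", 3, 0.1)]
        n_prime = {("PAN", 3, 0.1): nt + rng.integers(0, 3, size=5)}
        tables = _tables_for(combos, n_prime, nt, strata)
        with pytest.warns(UserWarning, match="coniferous"):
            cells, best = grid_search(tables, strata=(CONIFEROUS, BROADLEAF))
        assert best[CONIFEROUS] is None
        assert all(c.stratum == BROADLEAF for c in cells)

    def test_unclassified_pool_contains_every_plot(self, rng):
        nt = rng.integers(4, 60, size=9)
        strata = [CONIFEROUS] * 4 + [BROADLEAF] * 5
        combos = [("PAN", 3, 0.1)]
        n_prime = {("PAN", 3, 0.1): nt + rng.integers(-2, 3, size=9)}
        tables = _tables_for(combos, n_prime, nt, strata)
        cells, _ = grid_search(tables)
        by_stratum = {c.stratum: c.n for c in cells}
        assert by_stratum[UNCLASSIFIED] == 9
        assert by_stratum[CONIFEROUS] == 4
        assert by_stratum[BROADLEAF] == 5

    def test_noise_free_combination_wins_monte_carlo(self):
        # the noise-free 3x3 / 0.3 combination must win nearly always
        target = ("NIR", 3, 0.3)
        combos = [("NIR", w, t) for w in (3, 5) for t in (0.1, 0.3, 0.5)]
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            nt = rng.integers(4, 80, size=20)
            n_prime = {}
            for c in combos:
                if c == target:
                    n_prime[c] = nt
                else:
                    n_prime[c] = np.maximum(0, nt + rng.integers(-8, 9, size=20))
            tables = _tables_for(combos, n_prime, nt, [UNCLASSIFIED] * 20)
            _, best = grid_search(tables, strata=(UNCLASSIFIED,))
            b = best[UNCLASSIFIED]
            wins += (b.band, b.window_size, b.ndvi_threshold) == target
        assert wins >= 38  # >= 95% of 40 seeds

    def test_grid_dataframe_columns(self, rng):
        nt = rng.integers(4, 60, size=8)
        tables = _tables_for([("PAN", 3, 0.1)],
                             {("PAN", 3, 0.1): nt + rng.integers(0, 3, size=8)},
                             nt, [UNCLASSIFIED] * 8)
        cells, _ = grid_search(tables, strata=(UNCLASSIFIED,))
        df = grid_to_dataframe(cells)
        assert list(df.columns) == ["band", "window", "threshold", "stratum",
                                    "n", "r", "p", "significant"]


class TestFitDensityModel:
    def test_exact_linear_recovery(self):
        x = [1, 2, 3, 4, 5, 6]
        obs = make_observations(x, [2 + 3 * v for v in x])
        m = fit_density_model(obs, "linear")
        assert m.coefficients == pytest.approx((2.0, 3.0), abs=1e-9)
        assert m.r_squared == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0, abs=1e-9)

    def test_exact_quadratic_recovery(self):
        x = [0, 2, 4, 6, 8, 10]
        obs = make_observations(x, [1 + 0 * v + 0.5 * v * v for v in x])
        m = fit_density_model(obs, "quadratic")
        assert m.coefficients == pytest.approx((1.0, 0.0, 0.5), abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.integers(0, 60, size=73)
        y = np.round(5 + 0.8 * x + 0.01 * x ** 2 + rng.normal(0, 5, 73))
        obs = make_observations(x, y)
        for form, degree in (("linear", 1), ("quadratic", 2)):
            m = fit_density_model(obs, form)
            expected = oracle_ols(x.astype(float), y.astype(float), degree)
            np.testing.assert_allclose(m.coefficients, expected, atol=1e-8)

    def test_r_squared_equals_pearson_squared_for_linear(self, rng):
        x = rng.integers(0, 60, size=40)
        y = np.round(3 + 1.2 * x + rng.normal(0, 8, 40))
        obs = make_observations(x, y)
        m = fit_density_model(obs, "linear")
        r, _ = pearson_r(x.astype(float), y.astype(float))
        assert m.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_nested_model_sse_inequality(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            x = rng.integers(0, 60, size=n)
            if np.ptp(x) == 0:
                continue
            y = rng.normal(20, 10, size=n).round()
            obs = make_observations(x, y)
            lin = fit_density_model(obs, "linear")
            quad = fit_density_model(obs, "quadratic")
            sse_lin = lin.rmse ** 2 * n
            sse_quad = quad.rmse ** 2 * n
            assert sse_quad <= sse_lin + 1e-8
            assert quad.r_squared >= lin.r_squared - 1e-12

    def test_dof_bookkeeping(self, rng):
        x = rng.integers(0, 60, size=73)
        y = np.round(5 + 0.9 * x + rng.normal(0, 5, 73))
        m = fit_density_model(make_observations(x, y), "quadratic")
        assert m.dof == (2, 70)
        m2 = fit_density_model(make_observations(x, y), "linear")
        assert m2.dof == (1, 71)

    def test_f_and_p_match_scipy_reference(self, rng):
        # cross-check the F statistic against statsmodels-free direct formula
        from scipy import stats
        x = rng.integers(0, 60, size=50).astype(float)
        y = 5 + 0.8 * x + rng.normal(0, 6, 50)
        m = fit_density_model(make_observations(x, np.round(y)), "linear")
        assert m.p_value == pytest.approx(float(stats.f.sf(m.f_stat, *m.dof)), rel=1e-12)

    def test_constant_x_raises(self):
        obs = make_observations([5] * 10, range(10))
        with pytest.raises(SingularFitError):
            fit_density_model(obs, "linear")

    def test_too_few_observations_raises(self):
        obs = make_observations([1, 2], [3, 4])
        with pytest.raises(ValueError):
            fit_density_model(obs, "linear")

    def test_shapiro_p_attached(self, rng):
        x = rng.integers(0, 60, size=30)
        y = np.round(5 + x + rng.normal(0, 4, 30))
        m = fit_density_model(make_observations(x, y), "linear")
        assert 0.0 <= m.shapiro_p <= 1.0

    def test_parameter_recovery_quick(self, rng):
        # light version of the 200-seed acceptance suite
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.integers(0, 60, size=73).astype(float)
            y = 4 + 0.7 * x + 0.005 * x ** 2 + r.normal(0, 5, 73)
            m = fit_density_model(make_observations(x, np.round(y)), "quadratic")
            truth = (4, 0.7, 0.005)
            ok = all(abs(b - t) <= 3 * se
                     for b, t, se in zip(m.coefficients, truth, m.coef_se))
            hits += ok
        assert hits >= 17


class TestLoocv:
    def test_exact_linear_data(self):
        x = [1, 2, 3, 4, 5, 6, 7]
        obs = make_observations(x, [2 * v + 1 for v in x])
        r2, rmse = loocv(obs, "linear")
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_outlier_inflates_cv_rmse(self):
        x = list(range(10))
        y = [2 * v for v in x]
        y[-1] = 200  # gross outlier
        obs = make_observations(x, y)
        m = fit_density_model(obs, "linear")
        _, rmse_cv = loocv(obs, "linear")
        assert rmse_cv > m.rmse

    def test_predictions_match_brute_force_oracle(self, rng):
        x = rng.integers(0, 60, size=25).astype(float)
        y = np.round(5 + 0.9 * x + rng.normal(0, 6, 25))
        obs = make_observations(x, y)
        for form, degree in (("linear", 1), ("quadratic", 2)):
            got = loocv_predictions(obs, form)
            for i in range(len(obs)):
                keep = [j for j in range(len(obs)) if j != i]
                beta = oracle_ols(x[keep], y[keep], degree)
                expected = sum(b * x[i] ** k for k, b in enumerate(beta))
                assert got[i] == pytest.approx(expected, abs=1e-8)

    def test_needs_five_observations(self):
        with pytest.raises(ValueError):
            loocv(make_observations([1, 2, 3, 4], [1, 2, 3, 4]), "linear")

    def test_r2_cv_definition(self, rng):
        x = rng.integers(0, 60, size=30).astype(float)
        y = np.round(5 + 0.9 * x + rng.normal(0, 6, 30))
        obs = make_observations(x, y)
        preds = loocv_predictions(obs, "linear")
        press = float(np.sum((y - preds) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        r2, rmse = loocv(obs, "linear")
        assert r2 == pytest.approx(1 - press / sst, rel=1e-12)
        assert rmse == pytest.approx(math.sqrt(press / 30), rel=1e-12)


class TestCalibrateModels:
    def test_end_to_end_on_constructed_tables(self, rng):
        nt = rng.integers(4, 80, size=15)
        strata = [CONIFEROUS] * 7 + [BROADLEAF] * 8
        combos = [("NIR", 3, 0.1), ("NIR", 3, 0.3)]
        n_prime = {
            ("NIR", 3, 0.1): np.maximum(0, nt + rng.integers(-6, 7, size=15)),
            ("NIR", 3, 0.3): np.maximum(0, nt + rng.integers(-1, 2, size=15)),
        }
        tables = _tables_for(combos, n_prime, nt, strata)
        cells, best, models = calibrate_models(tables)
        assert set(models) <= {CONIFEROUS, BROADLEAF, UNCLASSIFIED}
        for stratum, by_form in models.items():
            assert set(by_form) == {"linear", "quadratic"}
            for m in by_form.values():
                assert m.r2_cv is not None
                assert m.rmse_cv is not None and m.rmse_cv >= 0
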