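import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from djpls.pls_stats import (
    assign_variables_to_components,
    correlation_filter,
    cross_validate_components,
    fit_pls,
    f_test_power,
    kfold_indices,
    model_p_value,
    required_sample_size,
    vif_filter,
    vif_values,
    vip_scores,
    zscore_columns,
)


def _frame(arr, prefix="x"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestZscore:
    def test_three_point_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, _ = zscore_columns(df)
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])  # ddof=1 denominator

    def test_idempotent_on_standardized(self, rng):
        df = _frame(rng.standard_normal((50, 3)))
        z1, _ = zscore_columns(df)
        z2, _ = zscore_columns(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_roundtrip(self, rng):
        df = _frame(rng.standard_normal((30, 4)) * 7 + 3)
        z, scaler = zscore_columns(df)
        assert np.allclose(scaler.inverse(z).to_numpy(), df.to_numpy(), atol=1e-12)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore_columns(df)


def _brute_force_correlation_filter(X, threshold):
    """Oracle: apply the published rule under every pair-processing order;
    return the set of removal sets reachable."""
    results = set()

    def step(cols):
        corr = X[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        pairs = [
            (i, j) for i in range(len(cols)) for j in range(i + 1, len(cols))
            if corr[i, j] > threshold
        ]
        if not pairs:
            results.add(frozenset(cols))
            return
        for i, j in pairs:
            mean_i = corr[i].sum() / (len(cols) - 1)
            mean_j = corr[j].sum() / (len(cols) - 1)
            drop = j if mean_j >= mean_i else i
            step([c for k, c in enumerate(cols) if k != drop])

    step(list(X.columns))
    return results


class TestCorrelationFilter:
    def test_duplicate_column_removes_exactly_one(self, rng):
        base = rng.standard_normal((30, 9))
        X = _frame(np.column_stack([base, base[:, 0]]))
        kept, report = correlation_filter(X)
        assert len(report.removed_by_correlation) == 1
        removed = report.removed_by_correlation[0][0]
        assert {removed, report.removed_by_correlation[0][1]} <= {"x0", "x9"}
        assert kept.shape[1] == 9

    def test_orthogonal_columns_untouched(self):
        X = _frame(np.eye(6))
        kept, report = correlation_filter(X)
        assert report.removed_by_correlation == []
        assert list(kept.columns) == list(X.columns)

    def test_matches_order_invariant_oracle(self, rng):
        # 5-column correlated instance: the documented processing order must
        # produce an outcome reachable by the rule under every order
        T = rng.standard_normal((40, 2))
        X = _frame(
            np.column_stack(
                [
                    T[:, 0],
                    T[:, 0] + 0.01 * rng.standard_normal(40),
                    T[:, 1],
                    T[:, 1] + 0.02 * rng.standard_normal(40),
                    rng.standard_normal(40),
                ]
            )
        )
        kept, report = correlation_filter(X, threshold=0.95)
        oracle_sets = _brute_force_correlation_filter(X, 0.95)
        assert frozenset(kept.columns) in oracle_sets

    def test_report_partition(self, rng):
        base = rng.standard_normal((30, 5))
        X = _frame(np.column_stack([base, base[:, 1]]))
        _, report = correlation_filter(X)
        report.check_partition(X.columns)


class TestVifFilter:
    def test_orthogonal_all_unity(self):
        # columns orthogonal *after centering*, so the correlation matrix
        # is exactly the identity
        A = np.random.default_rng(0).standard_normal((40, 5))
        q, _ = np.linalg.qr(A - A.mean(axis=0))
        X = _frame(q)
        vifs = vif_values(X)
        assert np.allclose(vifs, 1.0, atol=1e-8)
        kept, report = vif_filter(X)
        assert report.removed_by_vif == []
        assert kept.shape[1] == 5

    def test_exact_two_column_closed_form(self, rng):
        # construct columns with sample correlation exactly 0.9
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        a = (a - a.mean()) / a.std(ddof=1)
        b = b - b.mean()
        b -= (b @ a) / (a @ a) * a
        b /= b.std(ddof=1)
        X = pd.DataFrame({"a": a, "b": 0.9 * a + np.sqrt(1 - 0.81) * b})
        vifs = vif_values(X)
        assert np.allclose(vifs, 1.0 / (1.0 - 0.81), atol=1e-8)  # 5.263
        _, report = vif_filter(X, threshold=10.0)
        assert report.removed_by_vif == []

    def test_near_collinear_largest_removed_first(self, rng):
        x1 = rng.standard_normal(60)
        x2 = rng.standard_normal(60)
        x3 = x1 + x2 + 1e-3 * rng.standard_normal(60)
        x4 = rng.standard_normal(60)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3, "x4": x4})
        vifs = vif_values(X)
        # oracle: VIF via explicit regression of each column on the others
        for col in X.columns:
            others = X.drop(columns=[col]).to_numpy()
            others = (others - others.mean(0)) / others.std(0, ddof=1)
            target = (X[col] - X[col].mean()) / X[col].std(ddof=1)
            coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
            r2 = 1 - ((target - others @ coef) ** 2).sum() / (target**2).sum()
            assert vifs[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)
        _, report = vif_filter(X, threshold=10.0)
        assert report.removed_by_vif[0][0] == vifs.idxmax()
        report.check_partition(X.columns)

    def test_perfect_collinearity_infinite_vif(self, rng):
        x1 = rng.standard_normal(50)
        x2 = rng.standard_normal(50)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        kept, report = vif_filter(X)
        assert len(report.removed_by_vif) == 1
        assert kept.shape[1] == 2

    def test_underdetermined_fallback_is_finite(self, rng):
        X = _frame(rng.standard_normal((10, 20)))
        vifs = vif_values(X)
        assert np.all(np.isfinite(vifs))


class TestFitPls:
    def test_single_predictor_proportional(self):
        x = np.linspace(-1, 1, 20)
        X = pd.DataFrame({"x": x / x.std(ddof=1)})
        y = 3.0 * X["x"]
        model = fit_pls(X, y / y.std(ddof=1), 1)
        assert model.r2y_cumulative[-1] == pytest.approx(100.0, abs=1e-9)
        assert vip_scores(model).iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_equals_ols(self, rng):
        X = _frame(rng.standard_normal((25, 6)))
        y = pd.Series(rng.standard_normal(25))
        Xz, _ = zscore_columns(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        model = fit_pls(Xz, yz, 6)
        beta = np.linalg.lstsq(Xz.to_numpy(), yz.to_numpy(), rcond=None)[0]
        assert np.allclose(model.predict(Xz), Xz.to_numpy() @ beta, atol=1e-8)

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = _frame(rng.standard_normal((30, 8)))
        y = pd.Series(rng.standard_normal(30))
        Xz, _ = zscore_columns(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        model = fit_pls(Xz, yz, 4)
        sk = sklearn.PLSRegression(n_components=4, scale=False).fit(Xz, yz)
        assert np.allclose(model.predict(Xz), sk.predict(Xz).ravel(), atol=1e-10)

    def test_noiseless_two_latents_full_r2(self):
        from djpls.synthetic_data import default_latent_truth, generate_pls_dataset

        truth = default_latent_truth(
            n_samples=30, n_predictors=10, n_latent=2, block_sizes=(6, 4),
            noise_sd=0.0, population_r2=1.0 - 1e-12, seed=5,
        )
        X, y, _ = generate_pls_dataset(truth)
        Xz, _ = zscore_columns(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        model = fit_pls(Xz, yz, 2)
        assert model.r2y_cumulative[-1] == pytest.approx(100.0, abs=1e-7)

    def test_components_beyond_rank_rejected(self, rng):
        X = _frame(rng.standard_normal((10, 3)))
        X["x3"] = X["x0"] + X["x1"]  # rank 3
        y = pd.Series(rng.standard_normal(10))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, y, 4)

    def test_scores_orthogonal_r2_monotone(self, rng):
        X = _frame(rng.standard_normal((40, 10)))
        y = pd.Series(X.to_numpy()[:, :3] @ [1.0, 0.5, 0.2] + 0.3 * rng.standard_normal(40))
        Xz, _ = zscore_columns(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        model = fit_pls(Xz, yz, 6)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8
        assert np.all(np.diff(model.r2y_cumulative) >= -1e-10)


class TestVip:
    def test_orthogonal_single_relevant(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((60, 8))
        q, _ = np.linalg.qr(A - A.mean(axis=0))
        X = _frame(q * np.sqrt(59))
        y = X["x2"]
        model = fit_pls(X, (y - y.mean()) / y.std(ddof=1), 1)
        vip = vip_scores(model)
        assert vip["x2"] == pytest.approx(np.sqrt(8), rel=1e-6)
        others = vip.drop("x2")
        assert np.all(others < 1e-6)

    def test_mean_square_is_one(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = _frame(r.standard_normal((30, 7)))
            y = pd.Series(r.standard_normal(30))
            Xz, _ = zscore_columns(X)
            yz = (y - y.mean()) / y.std(ddof=1)
            model = fit_pls(Xz, yz, 3)
            assert (vip_scores(model) ** 2).mean() == pytest.approx(1.0, abs=1e-8)


class TestAssignment:
    def test_single_component_all_first(self, rng):
        X = _frame(rng.standard_normal((20, 5)))
        y = pd.Series(rng.standard_normal(20))
        Xz, _ = zscore_columns(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        table = assign_variables_to_components(fit_pls(Xz, yz, 1))
        assert (table["component"] == 1).all()

    def test_max_weight_rule(self):
        from djpls.pls_stats.pls import PLSModelResult

        model = PLSModelResult(
            columns=["a", "b"],
            weights=np.array([[0.9, 0.1], [0.1, 0.9]]),
            loadings=np.eye(2),
            scores=np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
            y_loadings=np.array([1.0, 0.5]),
            r2y_cumulative=np.array([60.0, 80.0]),
        )
        table = assign_variables_to_components(model)
        comp = dict(zip(table["variable"], table["component"]))
        assert comp == {"a": 1, "b": 2}

    def test_disjoint_blocks_recovered(self):
        from djpls.synthetic_data import default_latent_truth, generate_pls_dataset

        truth = default_latent_truth(
            n_samples=60, n_predictors=12, n_latent=2, block_sizes=(8, 4),
            noise_sd=0.05, population_r2=0.995, seed=2,
        )
        X, y, _ = generate_pls_dataset(truth)
        Xz, _ = zscore_columns(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        table = assign_variables_to_components(fit_pls(Xz, yz, 2))
        comp = dict(zip(table["variable"], table["component"]))
        block1 = {f"x{j:02d}" for j in range(8)}
        groups = {frozenset(v for v, c in comp.items() if c == a) for a in (1, 2)}
        assert frozenset(block1) in groups

    def test_sorted_by_component_then_vip(self, rng):
        X = _frame(rng.standard_normal((30, 6)))
        y = pd.Series(rng.standard_normal(30))
        Xz, _ = zscore_columns(X)
        yz = (y - y.mean()) / y.std(ddof=1)
        table = assign_variables_to_components(fit_pls(Xz, yz, 2))
        for _, grp in table.groupby("component"):
            assert np.all(np.diff(grp["VIP"]) <= 1e-12)


class TestCrossValidation:
    def test_fold_assignment_balanced_and_seeded(self):
        f1 = kfold_indices(43, 10, seed=3)
        f2 = kfold_indices(43, 10, seed=3)
        assert np.array_equal(f1, f2)
        sizes = np.bincount(f1)
        assert sizes.min() >= 4 and sizes.max() <= 5

    def test_k_exceeding_n_error(self):
        with pytest.raises(ValueError):
            kfold_indices(5, 10, 0)

    def test_noiseless_three_latents_selected(self):
        # noiseless X: rank 3, so components beyond 3 cannot improve and the
        # argmin (first of the tie) is exactly the latent dimension
        from djpls.synthetic_data import default_latent_truth, generate_pls_dataset

        truth = default_latent_truth(
            n_predictors=31, noise_sd=0.0, population_r2=1 - 1e-12, seed=1
        )
        X, y, _ = generate_pls_dataset(truth)
        cv = cross_validate_components(X, y, k=10, max_components=6, seed=1)
        assert cv.selected_components == 3
        assert cv.rmsecv[2] < cv.rmsecv[0]
        assert cv.rmsecv[2] < cv.rmsecv[1]

    def test_pure_noise_q2_nonpositive_majority(self):
        bad = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = _frame(r.standard_normal((40, 10)))
            y = pd.Series(r.standard_normal(40))
            cv = cross_validate_components(X, y, k=10, max_components=3, seed=seed)
            bad += np.all(cv.q2 <= 0.0)
        assert bad > n_seeds / 2

    def test_determinism(self):
        from djpls.synthetic_data import default_latent_truth, generate_pls_dataset

        X, y, _ = generate_pls_dataset(default_latent_truth(seed=4))
        a = cross_validate_components(X, y, seed=11, max_components=5)
        b = cross_validate_components(X, y, seed=11, max_components=5)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert np.array_equal(a.rmsecv, b.rmsecv)
        assert np.array_equal(a.q2, b.q2)


class TestModelPValue:
    def test_perfect_fit_tiny_p(self, rng):
        T = rng.standard_normal((30, 2))
        y = T[:, 0].copy()
        p = model_p_value(T, y, 1)
        assert p[0] < 1e-10

    def test_no_residual_df_error(self, rng):
        T = rng.standard_normal((10, 9))
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="degrees of freedom"):
            model_p_value(T, y, 9)

    def test_null_uniformity(self):
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(400):
            T = rng.standard_normal((25, 2))
            y = rng.standard_normal(25)
            ps.append(model_p_value(T, y, 2)[-1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRequiredSampleSize:
    def test_published_configuration(self):
        assert required_sample_size(0.43, 0.05, 0.80, 4) == 33

    def test_boundary_tiny_power_target(self):
        n = required_sample_size(5.0, 0.05, 0.06, 4)
        assert n <= 8  # just above predictors + 2

    def test_matches_grid_search_oracle(self):
        # independent brute-force sweep with the noncentral-F CDF
        f2, alpha, power, k = 0.15, 0.05, 0.80, 4
        oracle = None
        for n in range(k + 2, 500):
            df2 = n - k - 1
            crit = stats.f.isf(alpha, k, df2)
            if 1.0 - stats.ncf.cdf(crit, k, df2, f2 * n) >= power:
                oracle = n
                break
        assert required_sample_size(f2, alpha, power, k) == oracle

    def test_statsmodels_oracle(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        # statsmodels solves the same noncentral-F problem continuously
        solver = smp.FTestPowerF2()
        n_cont = solver.solve_power(
            effect_size=0.43, df_num=4, alpha=0.05, power=0.80
        )
        # solve_power returns df_denom; N = df_denom + k + 1
        assert required_sample_size(0.43, 0.05, 0.80, 4) == int(np.ceil(n_cont)) + 5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_sample_size(-0.1)
        with pytest.raises(ValueError):
            required_sample_size(0.3, alpha=1.5)

    def test_power_monotone_in_n(self):
        powers = [f_test_power(n, 0.43, 4) for n in range(10, 60)]
        assert np.all(np.diff(powers) > 0)
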