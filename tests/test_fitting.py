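import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicreg.errors import DataError
from omicreg.fitting import (
    GeneModel,
    choose_k,
    elastic_net_solve,
    fit_all,
    kkt_residual,
    lambda_max,
    make_split,
    models_from_json,
    models_to_json,
    select_lambda,
    soft_threshold,
    standardize,
)
from omicreg.io import RunConfig, substream
from omicreg.simulate import simulate_dataset

from conftest import fast_run_config, tiny_sim_config


def standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    return (X - X.mean(0)) / X.std(0)


class TestStandardize:
    def test_hand_example_population_sd(self):
        train = np.array([[1.0, 2.0, 3.0]])
        out, _, record = standardize(train)
        expected = np.array([-1.224744871391589, 0.0, 1.224744871391589])
        assert np.allclose(out[0], expected, atol=1e-12)
        assert record.ddof == 0
        assert record.sd[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotent(self, rng):
        row = rng.standard_normal(50)
        row = (row - row.mean()) / row.std()
        out, _, _ = standardize(row[None, :])
        assert np.allclose(out[0], row, atol=1e-12)

    def test_constant_row_flagged_and_zeroed(self):
        out, _, record = standardize(np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]))
        assert record.constant.tolist() == [True, False]
        assert np.all(out[0] == 0.0)

    def test_test_block_uses_train_parameters(self):
        train = np.array([[0.0, 2.0]])  # mean 1, sd 1
        test = np.array([[3.0]])
        _, test_s, _ = standardize(train, test)
        assert test_s[0, 0] == pytest.approx(2.0)

    def test_row_stats_after(self, rng):
        out, _, _ = standardize(rng.standard_normal((20, 100)) * 5 + 3)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out.std(axis=1), 1.0, atol=1e-10)


class TestMakeSplit:
    def _dataset(self, counts):
        n_samples = dict(counts)
        n_samples.setdefault("Normal", 10)
        return simulate_dataset(tiny_sim_config(n_samples=n_samples))[0]

    def test_45_samples_gives_36_9(self):
        ds = self._dataset({"Her2": 45})
        split = make_split(ds, fast_run_config())
        assert len(split.train["Her2"]) == 36 and len(split.test["Her2"]) == 9

    def test_125_samples_gives_100_25(self):
        ds = self._dataset({"Basal": 125})
        split = make_split(ds, fast_run_config())
        assert len(split.train["Basal"]) == 100 and len(split.test["Basal"]) == 25

    def test_deterministic(self):
        ds = self._dataset({"A": 50})
        a = make_split(ds, fast_run_config())
        b = make_split(ds, fast_run_config())
        assert a == b

    def test_partition(self):
        ds = self._dataset({"A": 37})
        split = make_split(ds, fast_run_config())
        train, test = set(split.train["A"]), set(split.test["A"])
        assert not train & test
        assert train | test == {s for s, p in zip(ds.sample_ids, ds.sample_phenotype) if p == "A"}

    def test_subsample_skips_small_phenotypes(self):
        ds = self._dataset({"Big": 60, "Small": 20})
        split = make_split(ds, fast_run_config(subsample_n=40))
        assert "Small" not in split.train and "Normal" not in split.train
        assert len(split.train["Big"]) + len(split.test["Big"]) == 40


class TestSolver:
    def test_univariate_closed_form(self):
        # beta = S(z, lam*alpha) / (1 + lam*(1-alpha)) with z = (1/n) x'y
        x = np.array([1.0, 2.0, 3.0])
        x = (x - x.mean()) / x.std()
        y = x.copy()  # z = 1.0
        _, beta = elastic_net_solve(x[:, None], y, alpha=0.5, lam=0.4)
        assert beta[0] == pytest.approx(soft_threshold(1.0, 0.2) / 1.2, abs=1e-8)
        assert beta[0] == pytest.approx(2.0 / 3.0, abs=1e-8)

    def test_zero_above_lambda_max(self, rng):
        X = standardized(rng, 30, 10)
        y = X @ rng.standard_normal(10)
        lmax = lambda_max(X, y, 0.5)
        _, beta = elastic_net_solve(X, y, 0.5, lmax * (1 + 1e-10))
        assert np.all(beta == 0.0)
        _, beta = elastic_net_solve(X, y, 0.5, lmax * 0.99)
        assert np.any(beta != 0.0)

    def test_lambda_zero_matches_least_squares(self, rng):
        X = standardized(rng, 60, 8)
        y = X @ rng.standard_normal(8) + 0.1 * rng.standard_normal(60) + 2.0
        b0, beta = elastic_net_solve(X, y, 0.5, 0.0, tol=1e-12)
        ones = np.column_stack([np.ones(60), X])
        ls = np.linalg.lstsq(ones, y, rcond=None)[0]
        assert b0 == pytest.approx(ls[0], abs=1e-6)
        assert np.allclose(beta, ls[1:], atol=1e-6)

    def test_kkt_residual_on_random_instances(self, rng):
        for _ in range(5):
            X = standardized(rng, 50, 200)
            beta_true = np.zeros(200)
            beta_true[:5] = rng.uniform(0.5, 1.5, 5)
            y = X @ beta_true + rng.standard_normal(50)
            lam = rng.uniform(0.05, 0.5)
            b0, beta = elastic_net_solve(X, y, 0.5, lam)
            assert kkt_residual(X, y, b0, beta, 0.5, lam) < 1e-6

    def test_intercept_identity(self, rng):
        X = standardized(rng, 40, 20)
        y = rng.standard_normal(40) + 1.5
        b0, beta = elastic_net_solve(X, y, 0.5, 0.2)
        assert b0 == pytest.approx(np.mean(y - X @ beta), abs=1e-10)

    def test_grouping_identical_predictors_split_weight(self, rng):
        x = standardized(rng, 50, 1)[:, 0]
        X = np.column_stack([x, x])
        y = x * 2.0 + 0.1 * rng.standard_normal(50)
        _, beta = elastic_net_solve(X, y, 0.5, 0.3, tol=1e-10)
        assert beta[0] == pytest.approx(beta[1], abs=1e-6)
        assert beta[0] != 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(DataError):
            elastic_net_solve(np.array([[np.inf], [1.0]]), np.array([1.0, 2.0]), 0.5, 0.1)

    def test_warm_start_agrees_with_cold(self, rng):
        X = standardized(rng, 40, 30)
        y = X @ np.r_[np.ones(3), np.zeros(27)] + 0.2 * rng.standard_normal(40)
        _, cold = elastic_net_solve(X, y, 0.5, 0.1, tol=1e-10)
        _, init = elastic_net_solve(X, y, 0.5, 0.5, tol=1e-10)
        _, warm = elastic_net_solve(X, y, 0.5, 0.1, tol=1e-10, beta_init=init)
        assert np.allclose(cold, warm, atol=1e-6)

    def test_training_mse_nondecreasing_in_lambda(self, rng):
        X = standardized(rng, 50, 20)
        y = X @ rng.standard_normal(20) + rng.standard_normal(50)
        grid = np.geomspace(10.0, 1e-3, 25)
        mses = []
        for lam in grid:
            b0, beta = elastic_net_solve(X, y, 0.5, lam)
            mses.append(np.mean((y - b0 - X @ beta) ** 2))
        assert np.all(np.diff(mses[::-1]) >= -1e-10)  # increasing with lambda

    def test_univariate_support_monotone_in_lambda(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        x = (x - x.mean()) / x.std()
        y = 0.8 * x
        lmax = lambda_max(x[:, None], y, 0.5)
        supports = []
        for lam in np.geomspace(lmax * 2, lmax * 0.01, 20):
            _, beta = elastic_net_solve(x[:, None], y, 0.5, lam)
            supports.append(int(beta[0] != 0.0))
        assert sorted(supports) == supports  # 0s then 1s as lambda decreases


class TestSoftThreshold:
    @given(
        z=st.floats(-100, 100, allow_nan=False),
        g=st.floats(0, 50, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_properties(self, z, g):
        s = soft_threshold(z, g)
        assert abs(s) <= abs(z) or s == 0.0
        if abs(z) <= g:
            assert s == 0.0
        else:
            assert s == pytest.approx(np.sign(z) * (abs(z) - g))


class TestSelectLambda:
    def test_fold_count_by_cohort_size(self):
        cfg = fast_run_config()
        assert choose_k(36, cfg) == 3
        assert choose_k(99, cfg) == 3
        assert choose_k(100, cfg) == 5
        assert choose_k(316, cfg) == 5

    def test_too_few_samples_rejected(self, rng):
        X = standardized(rng, 2, 5)
        with pytest.raises(DataError):
            select_lambda(X, rng.standard_normal(2), fast_run_config(), rng)

    def test_lambda_star_in_grid(self, rng):
        cfg = fast_run_config(cv_repeats=2, lambda_grid_size=15)
        X = standardized(rng, 40, 30)
        y = X[:, 0] + 0.5 * rng.standard_normal(40)
        lam, lambdas, curve = select_lambda(X, y, cfg, rng)
        assert lam in lambdas
        assert curve.shape == lambdas.shape
        assert lam == lambdas[np.argmin(curve)]

    def test_pure_noise_selects_heavy_penalty(self):
        cfg = fast_run_config(cv_repeats=5, lambda_grid_size=25)
        hits = 0
        for seed in range(5):
            rng = substream(seed, "noise-test")
            X = standardized(rng, 50, 100)
            y = rng.standard_normal(50)
            lam, lambdas, _ = select_lambda(X, y, cfg, rng)
            b0, beta = elastic_net_solve(X, y, cfg.alpha, lam)
            if np.count_nonzero(beta) <= 3:
                hits += 1
        assert hits >= 4

    def test_ties_break_to_larger_lambda(self, rng):
        # pure-noise flat region: all lambdas above the data lambda_max give
        # identical (zero) models, so the argmin must sit at the grid top of
        # any tie.
        cfg = fast_run_config(cv_repeats=2, lambda_grid_size=10, lambda_min=100.0, lambda_max=1000.0)
        X = standardized(rng, 30, 10)
        y = rng.standard_normal(30)
        lam, lambdas, curve = select_lambda(X, y, cfg, rng)
        assert lam == lambdas[np.argmin(curve)]
        flat = np.isclose(curve, curve.min())
        assert lam == lambdas[flat].max()


class TestFitAll:
    def test_models_and_exclusions(self, tiny_world):
        models = tiny_world["models"]
        ds = tiny_world["dataset"]
        assert len(models) == len(ds.target_genes) * len(ds.phenotypes)
        for m in models:
            assert m.gene not in m.coef  # own transcript never a predictor
            assert m.rmse_test >= 0.0
            assert m.lambda_selected in m.cv_lambdas
            omic_of = dict(zip(ds.feature_ids, ds.feature_omic))
            for omic, feats in m.selected_by_omic.items():
                assert all(omic_of[f] == omic for f in feats)

    def test_deterministic(self):
        sim = tiny_sim_config(n_samples={"A": 40, "Normal": 20}, n_target_genes=2)
        ds, _ = simulate_dataset(sim)
        cfg = fast_run_config(cv_repeats=2, lambda_grid_size=10)
        split = make_split(ds, cfg)
        a = fit_all(ds, split, cfg)
        b = fit_all(ds, split, cfg)
        assert [(m.gene, m.phenotype, m.coef, m.lambda_selected) for m in a] == [
            (m.gene, m.phenotype, m.coef, m.lambda_selected) for m in b
        ]

    def test_constant_gene_skipped(self, caplog):
        sim = tiny_sim_config(n_samples={"A": 30, "Normal": 20}, n_target_genes=2)
        ds, _ = simulate_dataset(sim)
        ds.values[ds.feature_row(ds.target_genes[0]), :] = 3.14
        cfg = fast_run_config(cv_repeats=2, lambda_grid_size=10)
        split = make_split(ds, cfg)
        with caplog.at_level("WARNING", logger="omicreg"):
            models = fit_all(ds, split, cfg)
        assert len(models) == 2  # 1 gene x 2 phenotypes
        assert "constant" in caplog.text

    def test_json_roundtrip(self, tiny_world, tmp_path):
        models = tiny_world["models"]
        models_to_json(models, tmp_path / "m.json")
        back = models_from_json(tmp_path / "m.json")
        assert len(back) == len(models)
        for a, b in zip(models, back):
            assert a.gene == b.gene and a.phenotype == b.phenotype
            assert a.coef == b.coef
            assert a.rmse_test == b.rmse_test and a.rmse_null == b.rmse_null
            assert np.array_equal(a.cv_lambdas, b.cv_lambdas)
            assert np.array_equal(a.cv_rmse, b.cv_rmse)
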