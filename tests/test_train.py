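"""Elastic-net solver, cross-validation, and the full training pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import enet_path

from micromet import (TrainConfig, cross_validate_metabolite,
                      elastic_net_objective, fit_elastic_net, fit_summary,
                      lambda_max, make_folds, train_all)
from micromet.train import CVWorkspace, _standardize

from conftest import make_table


def brute_force_elastic_net(X, y, alpha, lam):
    """Independent minimizer of the penalized objective.

    Splits coefficients into positive and negative parts so the L1 term is
    smooth, then solves the resulting box-constrained convex program with
    SLSQP from two starts (zeros and ridge-ish least squares).
    """
    from scipy.optimize import minimize

    n, p = X.shape
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)

    def objective(z):
        b0, bp, bn = z[0], z[1:p + 1], z[p + 1:]
        b = bp - bn
        resid = y - b0 - X @ b
        pen = alpha * (sd * (bp + bn)).sum() \
            + 0.5 * (1 - alpha) * ((sd * b) ** 2).sum()
        return 0.5 / n * (resid ** 2).sum() + lam * pen

    bounds = [(None, None)] + [(0, None)] * (2 * p)
    starts = [np.zeros(2 * p + 1)]
    ls = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=-1)[0]
    z0 = np.concatenate([[y.mean()], np.clip(ls, 0, None),
                         np.clip(-ls, 0, None)])
    starts.append(z0)
    best = np.inf
    for s in starts:
        res = minimize(objective, s, method="SLSQP", bounds=bounds,
                       options={"maxiter": 2000, "ftol": 1e-14})
        best = min(best, objective(res.x))
    return best


class TestFitElasticNet:
    def test_ols_limit_single_column(self):
        x = np.arange(1.0, 9.0).reshape(-1, 1)
        y = 2.0 * x[:, 0]
        coef, intercept = fit_elastic_net(x, y, alpha=0.5, lam=0.0)
        assert coef[0] == pytest.approx(2.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_full_shrinkage_at_lambda_max(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 4))
        y = X @ [1.0, -2.0, 0.5, 0.0] + 0.1 * rng.standard_normal(20)
        lmax = lambda_max(X, y, alpha=0.7)
        coef, intercept = fit_elastic_net(X, y, alpha=0.7, lam=lmax * 1.001)
        np.testing.assert_array_equal(coef, 0.0)
        assert intercept == pytest.approx(y.mean())
        # just inside the path, something activates
        coef, _ = fit_elastic_net(X, y, alpha=0.7, lam=lmax * 0.95)
        assert (coef != 0).any()

    def test_matches_brute_force_minimizer(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((8, 3))
        y = X @ [1.0, 0.0, -0.5] + 0.2 * rng.standard_normal(8)
        coef, b0 = fit_elastic_net(X, y, alpha=0.5, lam=0.1, tol=1e-8)
        ours = elastic_net_objective(X, y, coef, b0, 0.5, 0.1)
        oracle = brute_force_elastic_net(X, y, 0.5, 0.1)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_non_finite_inputs_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_elastic_net(X, np.ones(5), 0.5, 0.1)

    def test_sparsity_nonincreasing_along_path(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 5))
        y = X @ [2.0, -1.5, 1.0, 0.0, 0.0] + 0.3 * rng.standard_normal(40)
        Xs, _, _ = _standardize(X)
        lmax = lambda_max(X, y, 0.8)
        lams = np.geomspace(lmax, lmax * 1e-3, 60)
        _, coefs, _ = enet_path(Xs, y - y.mean(), l1_ratio=0.8, alphas=lams)
        nnz = (coefs != 0).sum(axis=0)  # along decreasing lambda
        assert (np.diff(nnz) >= 0).all()


class TestCrossValidation:
    def test_high_snr_recovery(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 10))
        y = X[:, 3] + 0.01 * X[:, 3].std() * rng.standard_normal(50)
        fit = cross_validate_metabolite(X, y, TrainConfig(seed=1))
        assert fit.cv_spearman > 0.95
        assert np.argmax(np.abs(fit.coefficients)) == 3

    def test_null_spearman_false_flag_rate(self):
        # independent noise responses: the false-flag rate at the 0.3
        # threshold must stay small. The score distribution itself is not
        # centered at zero: when CV zeroes every coefficient, out-of-fold
        # predictions are fold means, which anti-correlate with their own
        # held-out values — a conservative, well-known CV artifact
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 10))
        config = TrainConfig(alpha_grid=(0.5,), n_lambda=40, seed=2)
        workspace = CVWorkspace(X, make_folds(50, config))
        cvs = [cross_validate_metabolite(X, rng.standard_normal(50), config,
                                         workspace=workspace).cv_spearman
               for _ in range(100)]
        cvs = np.array(cvs)
        assert np.nanmedian(cvs) < 0.1  # no optimistic bias
        assert np.nanmean(cvs >= 0.3) < 0.10

    def test_loocv_equals_kfold_with_singleton_folds(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 3))
        y = X @ [1.0, 0.0, -1.0] + 0.1 * rng.standard_normal(5)
        a = cross_validate_metabolite(X, y, TrainConfig(cv_scheme="loocv",
                                                        seed=0))
        b = cross_validate_metabolite(X, y, TrainConfig(n_folds=5, seed=0))
        # both schemes assign each sample its own fold (n = k = 5)
        assert a.alpha == b.alpha
        assert a.lam == pytest.approx(b.lam)
        assert a.cv_spearman == pytest.approx(b.cv_spearman)

    def test_folds_deterministic_and_balanced(self):
        f1 = make_folds(25, TrainConfig(seed=9))
        f2 = make_folds(25, TrainConfig(seed=9))
        np.testing.assert_array_equal(f1, f2)
        counts = np.bincount(f1)
        assert counts.max() - counts.min() <= 1


class TestTrainAll:
    def test_planted_vs_noise_flagging(self, dataset, trained_model):
        wp = trained_model.well_predicted
        assert wp[dataset.planted_metabolite_ids].mean() >= 0.8
        assert wp[dataset.noise_metabolite_ids].mean() <= 0.2

    def test_metabolite_equal_to_feature_is_well_predicted(self):
        rng = np.random.default_rng(4)
        X = rng.dirichlet(np.ones(12) * 2, size=20)
        y1 = X[:, 0]
        Y = make_table(np.column_stack([y1, 1 - y1]), prefix_f="m")
        Xt = make_table(X)
        model = train_all(Xt, Y, TrainConfig(seed=4))
        assert model.cv_spearman["m0"] > 0.9
        assert bool(model.well_predicted["m0"])

    def test_impossible_threshold_flags_nothing(self, small_dataset):
        model = train_all(small_dataset.X, small_dataset.Y,
                          TrainConfig(seed=7, well_predicted_threshold=1.01,
                                      alpha_grid=(0.5,), n_lambda=30))
        assert not model.well_predicted.any()

    def test_seed_reproducibility(self, small_dataset):
        cfg = TrainConfig(seed=11, alpha_grid=(0.2, 1.0), n_lambda=30)
        m1 = train_all(small_dataset.X, small_dataset.Y, cfg)
        m2 = train_all(small_dataset.X, small_dataset.Y, cfg)
        pd.testing.assert_frame_equal(m1.coefficients, m2.coefficients)
        pd.testing.assert_series_equal(m1.cv_spearman, m2.cv_spearman)

    def test_summary_counts_consistent(self, trained_model):
        summ = fit_summary(trained_model)
        assert (summ["n_nonzero"]
                == summ["n_positive"] + summ["n_negative"]).all()
        assert summ["cv_spearman"].dropna().between(-1, 1).all()
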