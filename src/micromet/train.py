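"""Per-metabolite elastic-net training with cross-validated tuning.

One sparse linear model is fit per metabolite on rank-INT-transformed
predictor features against the arcsine-sqrt-transformed response. The mixing
parameter alpha (L1 fraction) and sparsity parameter lambda are chosen by
minimizing cross-validated mean squared error over a grid x path; each
metabolite is scored by the Spearman correlation between pooled out-of-fold
predictions and the observed response, and flagged well-predicted when that
correlation reaches the configured threshold (default 0.3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from .preprocess import (FilterPolicy, arcsine_sqrt, prevalence_abundance_filter,
                         rank_inverse_normal_table, tss_normalize,
                         variance_filter)
from .tables import AbundanceTable, WeightMatrix, align_samples


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within the iteration budget."""


@dataclass
class TrainConfig:
    """Hyperparameter search and cross-validation settings.

    alpha_grid : candidate L1 fractions in [0, 1]; 1 is the lasso.
    n_lambda : length of the geometric lambda path per alpha.
    cv_scheme : "kfold" (default, k = n_folds) or "loocv".
    n_folds : folds for k-fold CV (paper-standard 10).
    well_predicted_threshold : minimum cross-validated Spearman correlation
        for a metabolite to count as well predicted.
    lambda_min_ratio : smallest path lambda as a fraction of lambda_max;
        None picks 1e-3 when n > p and 1e-2 otherwise.
    """

    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.1, 2))
    n_lambda: int = 100
    cv_scheme: str = "kfold"
    n_folds: int = 10
    well_predicted_threshold: float = 0.3
    seed: int = 0
    lambda_min_ratio: float | None = None
    max_iter: int = 10_000
    # coordinate-descent duality-gap tolerance for the CV path search; loose
    # enough to keep the alpha x lambda grid fast, tight enough that the
    # selected pair and the refit coefficients are stable
    tol: float = 5e-4

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0:
            raise ValueError("alpha_grid must be non-empty")
        if any(a < 0 or a > 1 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 1]")
        if self.cv_scheme not in ("kfold", "loocv"):
            raise ValueError("cv_scheme must be 'kfold' or 'loocv'")
        if self.cv_scheme == "kfold" and self.n_folds < 2:
            raise ValueError("k-fold CV needs at least 2 folds")


@dataclass
class MetaboliteFit:
    """Selected model and CV score for a single metabolite."""

    metabolite_id: str
    coefficients: np.ndarray
    intercept: float
    alpha: float
    lam: float
    cv_spearman: float
    n_nonzero: int = field(init=False)
    n_positive: int = field(init=False)
    n_negative: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_positive = int((self.coefficients > 0).sum())
        self.n_negative = int((self.coefficients < 0).sum())
        self.n_nonzero = self.n_positive + self.n_negative


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns by their population (1/n) std.

    Constant columns get scale 1 so they stay finite; their coefficients are
    forced to zero downstream because a centered constant column is all-zero.
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def elastic_net_objective(X: np.ndarray, y: np.ndarray, coef: np.ndarray,
                          intercept: float, alpha: float, lam: float) -> float:
    """The penalized least-squares objective the solver minimizes.

    (1/2n)*RSS + lam * (alpha*||s.b||_1 + (1-alpha)/2*||s.b||_2^2), where s
    are the per-column population stds: predictors are standardized for the
    penalty while coefficients live on the input scale.
    """
    n = X.shape[0]
    resid = y - intercept - X @ coef
    sd = X.std(axis=0)
    b_std = coef * np.where(sd > 0, sd, 1.0)
    penalty = alpha * np.abs(b_std).sum() + 0.5 * (1 - alpha) * (b_std ** 2).sum()
    return float(0.5 / n * (resid ** 2).sum() + lam * penalty)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda that zeroes every coefficient at the given alpha."""
    n = X.shape[0]
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    yc = y - y.mean()
    lm = np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3))
    return float(max(lm, 1e-12))


def fit_elastic_net(X_t: np.ndarray, y_t: np.ndarray, alpha: float,
                    lam: float, max_iter: int = 10_000,
                    tol: float = 1e-4) -> tuple[np.ndarray, float]:
    """Solve one elastic-net problem; returns (coefficients, intercept).

    Predictors are internally standardized for the penalty and the
    coefficients are returned on the input scale. lam = 0 is the ordinary
    (minimum-norm) least-squares limit.
    """
    X_t = np.asarray(X_t, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    if not (np.isfinite(X_t).all() and np.isfinite(y_t).all()):
        raise ValueError("non-finite values in the training data")
    if X_t.shape[0] < 3:
        raise ValueError("need at least 3 samples to fit")
    Xs, mean, sd = _standardize(X_t)
    yc = y_t - y_t.mean()
    if lam == 0:
        b_std, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
    else:
        model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                           max_iter=max_iter, tol=tol)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(Xs, yc)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise ConvergenceError(
                f"elastic net did not converge within {max_iter} iterations "
                f"(alpha={alpha}, lambda={lam})")
        b_std = model.coef_
    coef = b_std / sd
    intercept = float(y_t.mean() - mean @ coef)
    return coef, intercept


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(n_samples: int, config: TrainConfig) -> np.ndarray:
    """Seeded fold labels, shared by every metabolite within one run."""
    if config.cv_scheme == "loocv":
        return np.arange(n_samples)
    k = config.n_folds
    if k > n_samples:
        raise ValueError(f"cannot make {k} folds from {n_samples} samples")
    rng = np.random.default_rng(config.seed)
    labels = np.resize(np.arange(k), n_samples)
    rng.shuffle(labels)
    return labels


class CVWorkspace:
    """Fold-wise standardized views of X, shared across metabolites.

    Standardizing the predictor matrix once per fold (instead of per
    metabolite x alpha) is what keeps the grid search tractable.
    """

    def __init__(self, X_t: np.ndarray, folds: np.ndarray):
        self.X = np.asarray(X_t, dtype=float)
        self.folds = np.asarray(folds)
        self.fold_ids = np.unique(self.folds)
        self.train_X: list[np.ndarray] = []
        self.test_X: list[np.ndarray] = []
        self.train_idx: list[np.ndarray] = []
        self.test_idx: list[np.ndarray] = []
        for f in self.fold_ids:
            te = np.where(self.folds == f)[0]
            tr = np.where(self.folds != f)[0]
            Xs_tr, mean, sd = _standardize(self.X[tr])
            self.train_X.append(np.asfortranarray(Xs_tr))
            self.test_X.append((self.X[te] - mean) / sd)
            self.train_idx.append(tr)
            self.test_idx.append(te)
        self.full_X, self.full_mean, self.full_sd = _standardize(self.X)


def _lambda_path(Xs: np.ndarray, yc: np.ndarray, alpha: float,
                 config: TrainConfig) -> np.ndarray:
    n, p = Xs.shape
    ratio = config.lambda_min_ratio
    if ratio is None:
        ratio = 1e-3 if n > p else 1e-2
    lmax = max(np.max(np.abs(Xs.T @ yc)) / (n * max(alpha, 1e-3)), 1e-12)
    return np.geomspace(lmax, lmax * ratio, config.n_lambda)


def cross_validate_metabolite(X_t: np.ndarray, y_t: np.ndarray,
                              config: TrainConfig,
                              metabolite_id: str = "metabolite",
                              workspace: CVWorkspace | None = None,
                              ) -> MetaboliteFit:
    """Grid-search (alpha, lambda) by CV MSE, refit, and score by Spearman.

    The selection criterion is the cross-validated Gaussian deviance (mean
    squared error); cv_spearman is computed on the pooled out-of-fold
    predictions at the selected pair, which stays well defined under LOOCV.
    """
    X_t = np.asarray(X_t, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    if workspace is None:
        workspace = CVWorkspace(X_t, make_folds(len(y_t), config))
    n = len(y_t)
    yc_full = y_t - y_t.mean()

    best = None  # (mse, alpha_pos, lam_pos, alpha, lam, oof)
    for a_pos, alpha in enumerate(config.alpha_grid):
        path = _lambda_path(workspace.full_X, yc_full, alpha, config)
        oof = np.zeros((n, len(path)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for k in range(len(workspace.fold_ids)):
                tr, te = workspace.train_idx[k], workspace.test_idx[k]
                ytr = y_t[tr]
                _, coefs, _ = enet_path(workspace.train_X[k], ytr - ytr.mean(),
                                        l1_ratio=alpha, alphas=path,
                                        max_iter=config.max_iter,
                                        tol=config.tol, copy_X=False,
                                        check_input=True)
                oof[te] = workspace.test_X[k] @ coefs + ytr.mean()
        mse = ((oof - y_t[:, None]) ** 2).mean(axis=0)
        l_pos = int(np.argmin(mse))
        if best is None or mse[l_pos] < best[0]:
            best = (mse[l_pos], alpha, float(path[l_pos]), oof[:, l_pos].copy())

    _, sel_alpha, sel_lam, sel_oof = best
    if np.std(sel_oof) == 0 or np.std(y_t) == 0:
        cv_sp = float("nan")
    else:
        cv_sp = float(stats.spearmanr(sel_oof, y_t).statistic)

    coef, intercept = fit_elastic_net(X_t, y_t, sel_alpha, sel_lam,
                                      max_iter=config.max_iter,
                                      tol=config.tol)
    return MetaboliteFit(metabolite_id=metabolite_id, coefficients=coef,
                         intercept=intercept, alpha=sel_alpha, lam=sel_lam,
                         cv_spearman=cv_sp)


# ---------------------------------------------------------------------------
# Full training pipeline
# ---------------------------------------------------------------------------

def train_all(X: AbundanceTable, Y: AbundanceTable, config: TrainConfig,
              policy: FilterPolicy | None = None) -> WeightMatrix:
    """Normalize, filter, transform, and fit one model per metabolite.

    Poorly predicted metabolites are retained in the output but flagged;
    the weight matrix covers the union of predictor features that carry a
    nonzero coefficient in any model. Deterministic given config.seed.
    """
    policy = policy or FilterPolicy()
    X, Y = align_samples(X, Y)
    Xn = tss_normalize(X)
    Yn = tss_normalize(Y)
    Xf = prevalence_abundance_filter(Xn, policy)
    Yf = prevalence_abundance_filter(Yn, policy)
    # constant predictors cannot be rank-transformed; always dropped
    Xf = variance_filter(Xf, 0.0)
    if policy.min_variance > 0:
        Xf = variance_filter(Xf, policy.min_variance)
        Yf = variance_filter(Yf, policy.min_variance)

    Z = rank_inverse_normal_table(Xf).to_numpy()
    Yt = arcsine_sqrt(Yf.values)

    folds = make_folds(Xf.n_samples, config)
    workspace = CVWorkspace(Z, folds)

    fits = [cross_validate_metabolite(Z, Yt[:, j], config,
                                      metabolite_id=mid, workspace=workspace)
            for j, mid in enumerate(Yf.feature_ids)]

    coef_mat = np.column_stack([f.coefficients for f in fits])
    used = (coef_mat != 0).any(axis=1)
    feature_ids = [fid for fid, u in zip(Xf.feature_ids, used) if u]
    mets = [f.metabolite_id for f in fits]
    cv = np.array([f.cv_spearman for f in fits])
    well = np.where(np.isnan(cv), False,
                    cv >= config.well_predicted_threshold)
    return WeightMatrix(
        coefficients=pd.DataFrame(coef_mat[used], index=feature_ids,
                                  columns=mets),
        intercepts=pd.Series([f.intercept for f in fits], index=mets),
        alpha=pd.Series([f.alpha for f in fits], index=mets),
        lam=pd.Series([f.lam for f in fits], index=mets),
        cv_spearman=pd.Series(cv, index=mets),
        well_predicted=pd.Series(well, index=mets),
        threshold=config.well_predicted_threshold,
    )


def fit_summary(model: WeightMatrix) -> pd.DataFrame:
    """Per-metabolite summary table (alpha, lambda, score, size, flag)."""
    nz = (model.coefficients != 0)
    return pd.DataFrame({
        "alpha": model.alpha,
        "lambda": model.lam,
        "cv_spearman": model.cv_spearman,
        "n_nonzero": nz.sum(axis=0),
        "n_positive": (model.coefficients > 0).sum(axis=0),
        "n_negative": (model.coefficients < 0).sum(axis=0),
        "well_predicted": model.well_predicted,
    })
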