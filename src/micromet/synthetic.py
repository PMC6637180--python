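"""Synthetic paired feature/metabolite tables with known ground truth.

The generator emulates the statistical structure of community sequencing
profiles: sparse, heavy-tailed (log-normal) compositional feature tables
with per-feature prevalence, paired with metabolite tables built from a
known sparse linear map. Signal is planted on exactly the scales the model
fits — rank-INT-transformed features and arcsine-sqrt-transformed responses
— so parameter and support recovery are well-posed oracles. A "raw" signal
mode plants the linear map on untransformed abundances instead, to probe
robustness to model misspecification.

The metabolite table carries one extra remainder column (``M_REST``) holding
the unassigned compositional mass, mirroring the unannotated bulk of real
community metabolomes; it keeps rows summing to 1 without distorting the
planted per-metabolite signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import inverse_arcsine_sqrt, rank_inverse_normal_table
from .tables import AbundanceTable

#: Name of the synthetic metabolite column holding the unassigned
#: compositional mass; it belongs to neither the planted nor the noise set.
REMAINDER_ID = "M_REST"


@dataclass
class _FeatureModel:
    """Generative parameters of the feature table (kept for drift cohorts)."""

    log_mean: np.ndarray      # per-feature location of the log-normal
    prevalence: np.ndarray    # per-feature presence probability
    log_sd: float
    loadings: np.ndarray      # features x k latent community gradients


@dataclass
class SyntheticDataset:
    """Paired tables plus the planted truth."""

    X: AbundanceTable
    Y: AbundanceTable
    true_weights: pd.DataFrame          # features x metabolites, sparse
    true_intercepts: pd.Series
    planted_metabolite_ids: list[str]
    noise_metabolite_ids: list[str]
    noise_sd: float
    effect_sd: float
    seed: int
    feature_model: _FeatureModel
    signal_mode: str


def _draw_features(n_samples: int, fm: _FeatureModel, rng: np.random.Generator,
                   sample_prefix: str) -> pd.DataFrame:
    p = fm.log_mean.size
    factors = rng.standard_normal((n_samples, fm.loadings.shape[1]))
    logs = fm.log_mean + factors @ fm.loadings.T \
        + fm.log_sd * rng.standard_normal((n_samples, p))
    vals = np.exp(logs)
    mask = rng.random((n_samples, p)) < fm.prevalence
    vals = vals * mask
    dead = vals.sum(axis=1) == 0
    if dead.any():  # pathological row: drop its sparsity mask
        vals[dead] = np.exp(logs[dead])
    vals /= vals.sum(axis=1, keepdims=True)
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    features = [f"F{j + 1:04d}" for j in range(p)]
    return pd.DataFrame(vals, index=samples, columns=features)


def _responses(Xdf: pd.DataFrame, weights: np.ndarray, intercepts: np.ndarray,
               planted: np.ndarray, noise_sd: float, effect_sd: float,
               signal_mode: str, rng: np.random.Generator,
               metabolite_ids: list[str]) -> pd.DataFrame:
    n = Xdf.shape[0]
    m = weights.shape[1]
    if signal_mode == "transformed":
        basis = rank_inverse_normal_table(
            AbundanceTable(Xdf, is_normalized=False),
            constant_to_zero=True).to_numpy()
    else:  # linear in the raw relative abundances (misspecified probe)
        basis = Xdf.to_numpy()
        col_sd = basis.std(axis=0)
        basis = basis / np.where(col_sd > 0, col_sd, 1.0)
    y_t = np.tile(intercepts, (n, 1)) + basis @ weights
    noise = np.where(planted, noise_sd, effect_sd)
    y_t += rng.standard_normal((n, m)) * noise
    # the inverse transform clamps t below 0: metabolites hitting the floor
    # of the composition read as absent, as in real profiles
    y = inverse_arcsine_sqrt(y_t)
    # a remainder column absorbs the unassigned compositional mass (the
    # analogue of unannotated spectral features), so every modelled
    # metabolite keeps exactly sin^2(t) as its relative abundance and rows
    # still sum to 1; rows that would overflow are rescaled (rare by design
    # of the intercept budget)
    total = y.sum(axis=1, keepdims=True)
    overflow = total > 0.98
    if overflow.any():
        y = np.where(overflow, y * (0.98 / total), y)
        total = y.sum(axis=1, keepdims=True)
    y = np.column_stack([y, 1.0 - total[:, 0]])
    return pd.DataFrame(y, index=Xdf.index,
                        columns=[*metabolite_ids, REMAINDER_ID])


def generate(n_samples: int = 50, n_features: int = 200,
             n_metabolites: int = 30, frac_planted: float = 0.67,
             support_size: int = 8, noise_sd: float = 0.05, seed: int = 0,
             zero_fraction: float = 0.3, effect_sd: float = 0.1,
             log_mean_sd: float = 1.5, log_sd: float = 1.0,
             n_latent_factors: int = 3, latent_factor_sd: float = 0.7,
             signal_mode: str = "transformed") -> SyntheticDataset:
    """Generate a paired training dataset with planted sparse signal.

    Features follow a masked log-normal compositional model: per-feature
    log-abundance locations spread by ``log_mean_sd`` (skew across features),
    per-feature prevalence drawn so the expected zero fraction is
    ``zero_fraction``. For each planted metabolite a ``support_size``-sparse
    mixed-sign weight vector acts on the transformed features, scaled so the
    signal has standard deviation ``effect_sd`` on the arcsine-sqrt scale,
    plus Gaussian noise of sd ``noise_sd``. Noise metabolites vary
    independently of X with sd ``effect_sd``. Deterministic given ``seed``.

    ``n_latent_factors`` community gradients (loading sd
    ``latent_factor_sd`` on the log scale) induce the correlated population
    structure real communities show, which is what the representativeness
    score keys on.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples")
    if not 0 < support_size < n_features:
        raise ValueError("support_size must be in (0, n_features)")
    if not 0 <= zero_fraction <= 0.5:
        raise ValueError("zero_fraction must lie in [0, 0.5] (prevalence is "
                         "drawn uniformly on [1 - 2*zero_fraction, 1])")
    if signal_mode not in ("transformed", "raw"):
        raise ValueError("signal_mode must be 'transformed' or 'raw'")
    rng = np.random.default_rng(seed)

    fm = _FeatureModel(
        log_mean=rng.normal(0.0, log_mean_sd, size=n_features),
        prevalence=rng.uniform(1 - 2 * zero_fraction, 1.0, size=n_features),
        log_sd=log_sd,
        loadings=rng.normal(0.0, latent_factor_sd,
                            size=(n_features, n_latent_factors)),
    )
    Xdf = _draw_features(n_samples, fm, rng, "S")

    n_planted = int(round(frac_planted * n_metabolites))
    metabolite_ids = [f"M{j + 1:03d}" for j in range(n_metabolites)]
    planted_flags = np.zeros(n_metabolites, dtype=bool)
    planted_flags[:n_planted] = True

    # supports are drawn from well-observed features so the planted signal
    # survives the prevalence filter
    observed_frac = (Xdf.to_numpy() > 0).mean(axis=0)
    eligible = np.where(observed_frac >= 0.9)[0]
    if eligible.size < support_size:
        eligible = np.argsort(observed_frac)[-max(support_size, 1):]

    # half the compositional budget is reserved for the remainder column so
    # per-metabolite values stay clear of the simplex boundary
    base_level = float(np.arcsin(np.sqrt(0.5 / n_metabolites)))
    intercepts = base_level + rng.normal(0.0, 0.02, size=n_metabolites)

    if signal_mode == "transformed":
        basis = rank_inverse_normal_table(
            AbundanceTable(Xdf, is_normalized=False),
            constant_to_zero=True).to_numpy()
    else:
        basis = Xdf.to_numpy()
        col_sd = basis.std(axis=0)
        basis = basis / np.where(col_sd > 0, col_sd, 1.0)

    weights = np.zeros((n_features, n_metabolites))
    for j in range(n_planted):
        support = rng.choice(eligible, size=support_size, replace=False)
        w = rng.uniform(0.5, 1.5, size=support_size) \
            * rng.choice([-1.0, 1.0], size=support_size)
        signal = basis[:, support] @ w
        sd = signal.std()
        weights[support, j] = w * (effect_sd / sd if sd > 0 else 1.0)

    Ydf = _responses(Xdf, weights, intercepts, planted_flags, noise_sd,
                     effect_sd, signal_mode, rng, metabolite_ids)

    return SyntheticDataset(
        X=AbundanceTable(Xdf, is_normalized=True),
        Y=AbundanceTable(Ydf, is_normalized=True),
        true_weights=pd.DataFrame(weights, index=list(Xdf.columns),
                                  columns=metabolite_ids),
        true_intercepts=pd.Series(intercepts, index=metabolite_ids),
        planted_metabolite_ids=metabolite_ids[:n_planted],
        noise_metabolite_ids=metabolite_ids[n_planted:],
        noise_sd=noise_sd,
        effect_sd=effect_sd,
        seed=seed,
        feature_model=fm,
        signal_mode=signal_mode,
    )


def make_validation_cohort(dataset: SyntheticDataset, n_new_samples: int,
                           drift: float, seed: int,
                           ) -> tuple[AbundanceTable, AbundanceTable]:
    """Draw a held-out cohort whose feature distribution drifts away.

    drift = 0 reproduces the training feature distribution; drift = 1 swaps
    in a freshly drawn, unrelated one. The held-out true metabolite table is
    produced by the same planted map (with the training noise level) so
    representativeness-versus-accuracy experiments are possible.
    """
    if not 0 <= drift <= 1:
        raise ValueError("drift must lie in [0, 1]")
    if n_new_samples < 2:
        raise ValueError("a prediction cohort needs at least 2 samples")
    rng = np.random.default_rng(seed)
    fm0 = dataset.feature_model
    p = fm0.log_mean.size
    fresh = _FeatureModel(
        log_mean=rng.normal(0.0, np.std(fm0.log_mean) or 1.0, size=p),
        prevalence=rng.uniform(fm0.prevalence.min(), 1.0, size=p),
        log_sd=fm0.log_sd,
        loadings=rng.normal(0.0, np.std(fm0.loadings) or 1.0,
                            size=fm0.loadings.shape),
    )
    fm = _FeatureModel(
        log_mean=(1 - drift) * fm0.log_mean + drift * fresh.log_mean,
        prevalence=(1 - drift) * fm0.prevalence + drift * fresh.prevalence,
        log_sd=fm0.log_sd,
        loadings=(1 - drift) * fm0.loadings + drift * fresh.loadings,
    )
    Xdf = _draw_features(n_new_samples, fm, rng, "V")
    planted_flags = np.array([m in set(dataset.planted_metabolite_ids)
                              for m in dataset.true_weights.columns])
    Ydf = _responses(Xdf, dataset.true_weights.to_numpy(),
                     dataset.true_intercepts.to_numpy(), planted_flags,
                     dataset.noise_sd, dataset.effect_sd,
                     dataset.signal_mode, rng,
                     list(dataset.true_weights.columns))
    return (AbundanceTable(Xdf, is_normalized=True),
            AbundanceTable(Ydf, is_normalized=True))
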