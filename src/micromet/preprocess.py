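"""Normalization, filtering, and variance-stabilizing transforms.

Predictor features are quantile-mapped to standard-normal scores (rank-based
inverse normal transform); metabolite responses are arcsine-square-root
transformed, with an exact inverse for back-transforming predictions onto
the relative-abundance scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, TableValidationError


@dataclass
class FilterPolicy:
    """Feature quality-control thresholds.

    min_mean_abundance : relative-abundance fraction a feature must exceed
        (default 1e-4, i.e. 0.01%).
    min_prevalence : fraction of samples in which it must do so (default 0.10).
    min_variance : features with across-sample variance <= this are dropped
        when the variance filter runs (default 0 drops only constant features).
    alt_low_abundance_threshold : the low-biomass / non-gut abundance setting
        (1e-6, i.e. 0.0001%), substituted for min_mean_abundance when a
        16S-based non-gut profile is analyzed.
    """

    min_mean_abundance: float = 1e-4
    min_prevalence: float = 0.10
    min_variance: float = 0.0
    alt_low_abundance_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.min_mean_abundance, self.min_variance,
               self.alt_low_abundance_threshold) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 <= self.min_prevalence <= 1:
            raise ValueError("min_prevalence must be in [0, 1]")


def tss_normalize(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: divide each sample row by its sum.

    Idempotent; proportions within a row are preserved. All-zero rows are
    rejected because they have no compositional representation.
    """
    vals = table.values
    sums = vals.sum(axis=1)
    zero = sums == 0
    if zero.any():
        raise TableValidationError(
            f"cannot normalize all-zero sample rows: "
            f"{list(table.data.index[zero][:5])}")
    out = table.data.div(sums, axis=0)
    return AbundanceTable(out, is_normalized=True)


def prevalence_abundance_filter(table: AbundanceTable,
                                policy: FilterPolicy,
                                abundance_threshold: float | None = None,
                                ) -> AbundanceTable:
    """Keep features exceeding an abundance threshold in enough samples.

    A feature is retained iff its relative abundance is strictly greater
    than the threshold in at least ``ceil(min_prevalence * n_samples)``
    samples. Rows are NOT renormalized afterwards, so retained features stay
    on the original relative-abundance scale.
    """
    if not table.is_normalized:
        raise TableValidationError(
            "prevalence/abundance filtering requires a normalized table")
    thr = (policy.min_mean_abundance if abundance_threshold is None
           else abundance_threshold)
    n = table.n_samples
    need = math.ceil(policy.min_prevalence * n)
    hits = (table.values > thr).sum(axis=0)
    keep = hits >= need
    if not keep.any():
        raise TableValidationError(
            "no features pass the prevalence/abundance filter; consider "
            "relaxing min_mean_abundance or min_prevalence")
    return AbundanceTable(table.data.loc[:, keep], table.is_normalized,
                          is_filtered=True)


def variance_filter(table: AbundanceTable,
                    min_variance: float = 0.0) -> AbundanceTable:
    """Drop features whose across-sample variance (ddof=1) is <= min_variance.

    At the default 0 this removes exactly the features that do not vary
    over the available samples.
    """
    var = table.data.var(axis=0, ddof=1).to_numpy()
    vals = table.values
    constant = (vals == vals[0]).all(axis=0)  # exact, immune to roundoff
    keep = (var > min_variance) & ~constant
    if not keep.any():
        raise TableValidationError(
            "no features pass the variance filter; consider lowering "
            "min_variance")
    return AbundanceTable(table.data.loc[:, keep], table.is_normalized,
                          is_filtered=True)


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, z_i = Phi^-1((r_i - 0.5)/n).

    r_i is the 1-based rank with ties given average ranks (the GenABEL
    ``rntransform`` convention). Strictly rank-preserving on untied values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("rank_inverse_normal expects a 1-D vector")
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 observations to rank-transform")
    if np.all(values == values[0]):
        raise ValueError("constant vector cannot be rank-transformed; "
                         "remove constant features first (variance_filter)")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def rank_inverse_normal_table(table: AbundanceTable,
                              constant_to_zero: bool = False) -> pd.DataFrame:
    """Column-wise rank-INT of an abundance table.

    With ``constant_to_zero`` constant columns map to 0 (the center of the
    transform's range) instead of raising — used at prediction time where
    model features absent from a new cohort are zero-filled.
    """
    out = np.empty(table.data.shape, dtype=float)
    vals = table.values
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.all(col == col[0]):
            if not constant_to_zero:
                raise ValueError(
                    f"feature {table.data.columns[j]!r} is constant; "
                    "apply variance_filter first")
            out[:, j] = 0.0
        else:
            out[:, j] = rank_inverse_normal(col)
    return pd.DataFrame(out, index=table.data.index,
                        columns=table.data.columns)


def arcsine_sqrt(y) -> np.ndarray | float:
    """Variance-stabilizing transform for proportions: asin(sqrt(y))."""
    arr = np.asarray(y, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("arcsine_sqrt input must lie in [0, 1]")
    out = np.arcsin(np.sqrt(np.clip(arr, 0.0, 1.0)))
    return out if out.ndim else float(out)


def inverse_arcsine_sqrt(t) -> np.ndarray | float:
    """Back-transform sin(t)^2, clamping t into [0, pi/2] first.

    Clamping guarantees the back-transformed prediction is a valid
    proportion regardless of how far the linear predictor strays.
    """
    arr = np.asarray(t, dtype=float)
    out = np.sin(np.clip(arr, 0.0, np.pi / 2)) ** 2
    return out if out.ndim else float(out)
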