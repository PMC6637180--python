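"""Apply a trained weight matrix to new sequence-feature tables.

Prediction mirrors the training pipeline: normalize, rank-INT the features
within the new cohort, take the per-metabolite linear combination, and
back-transform through the inverse arcsine-sqrt so predictions land on the
relative-abundance scale in [0, 1].

Because the rank-based transform is cohort-relative, prediction requires at
least two samples; training statistics cannot be transferred to rank a
single new sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import inverse_arcsine_sqrt, rank_inverse_normal_table, tss_normalize
from .tables import AbundanceTable, TableValidationError, WeightMatrix


@dataclass
class PredictionResult:
    """Predicted metabolite relative abundances plus coverage diagnostics."""

    predicted: pd.DataFrame              # samples x metabolites, in [0, 1]
    missing_feature_ids: list[str]       # model features absent from input
    n_ignored_features: int              # input features unknown to the model
    coverage_fraction: pd.Series         # per-sample fraction of model
    #                                      features observed (> 0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.predicted.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.predicted.columns)


def align_features(new_X: AbundanceTable, model: WeightMatrix,
                   ) -> tuple[pd.DataFrame, list[str], int]:
    """Reorder new-table columns to the model's features.

    Model features missing from the new table are zero-filled and reported;
    new features unknown to the model are ignored and counted. Disjoint
    feature sets are an error (run the representativeness check instead).
    """
    have = set(new_X.feature_ids)
    missing = [f for f in model.feature_ids if f not in have]
    if len(missing) == len(model.feature_ids):
        raise TableValidationError(
            "no overlap between model features and the new table; check "
            "representativeness (RTSI) of these samples before predicting")
    n_ignored = len(have - set(model.feature_ids))
    aligned = new_X.data.reindex(columns=model.feature_ids, fill_value=0.0)
    return aligned, missing, n_ignored


def predict(new_X: AbundanceTable, model: WeightMatrix) -> PredictionResult:
    """Predict metabolite relative abundances for a new cohort.

    Pipeline: align features -> TSS normalize over the model's features ->
    rank-INT within the new cohort (constant columns, including zero-filled
    missing features, map to the transform's center 0) -> linear predictor
    per metabolite -> inverse arcsine-sqrt. Aligning before normalization
    makes predictions independent of any input features the model does not
    know about. Deterministic.
    """
    if new_X.n_samples < 2:
        raise TableValidationError(
            "prediction needs at least 2 samples: the rank-based inverse "
            "normal transform is computed within the new cohort")
    if not new_X.is_normalized:
        warnings.warn("input table is not normalized; applying total-sum "
                      "scaling over the model features", stacklevel=2)
    aligned, missing, n_ignored = align_features(new_X, model)

    coverage = (aligned > 0).mean(axis=1)
    normalized = tss_normalize(AbundanceTable(aligned, is_normalized=False))
    Z = rank_inverse_normal_table(normalized, constant_to_zero=True)
    linear = Z.to_numpy() @ model.coefficients.to_numpy() \
        + model.intercepts.to_numpy()
    predicted = pd.DataFrame(inverse_arcsine_sqrt(linear),
                             index=aligned.index,
                             columns=model.metabolite_ids)
    return PredictionResult(predicted=predicted,
                            missing_feature_ids=missing,
                            n_ignored_features=n_ignored,
                            coverage_fraction=coverage)
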