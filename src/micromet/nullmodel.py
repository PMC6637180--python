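"""Shuffled-data significance testing.

The null procedure breaks every feature-metabolite linkage by independently
permuting each feature column across samples in both tables, renormalizing
each sample row afterwards so the data keep their compositional structure,
and re-running the full training pipeline. The fraction of metabolites that
still come out "well predicted" on shuffled data estimates the false-flag
rate of the Spearman threshold; the paired well-predicted indicators of the
true and a shuffled run are compared with McNemar's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import FilterPolicy, tss_normalize
from .tables import AbundanceTable
from .train import TrainConfig, train_all

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


@dataclass
class NullRunSummary:
    """Well-predicted fractions under the permutation null."""

    n_iterations: int
    null_fractions: np.ndarray       # per-iteration well-predicted fraction
    observed_fraction: float         # fraction on the unshuffled data
    mcnemar_p: float                 # true vs first permuted run
    seed: int

    @property
    def mean_null_fraction(self) -> float:
        return float(np.mean(self.null_fractions))


def permute_and_renormalize(table: AbundanceTable, seed,
                            mode: str = "per-feature",
                            renormalize: bool = True) -> AbundanceTable:
    """Shuffle abundances across samples, then renormalize each row.

    mode "per-feature" (default) permutes every feature column independently,
    destroying all feature-feature and feature-metabolite structure while
    preserving each column's value multiset; "sample-label" applies one row
    permutation, preserving within-sample structure. Rows are renormalized
    to sum to 1 afterwards (``renormalize=False`` exposes the raw permuted
    values, whose column multisets equal the originals exactly). A
    permutation that leaves a row all-zero is redrawn (logged), up to a
    retry cap.
    """
    if mode not in ("per-feature", "sample-label"):
        raise ValueError("mode must be 'per-feature' or 'sample-label'")
    if not table.is_normalized:
        table = tss_normalize(table)
    rng = np.random.default_rng(seed)
    vals = table.values
    n, p = vals.shape
    for attempt in range(_MAX_REDRAWS):
        if mode == "sample-label":
            out = vals[rng.permutation(n)]
        else:
            out = np.empty_like(vals)
            for j in range(p):
                out[:, j] = vals[rng.permutation(n), j]
        sums = out.sum(axis=1)
        if (sums > 0).all():
            if not renormalize:
                return AbundanceTable(
                    pd.DataFrame(out, index=table.data.index,
                                 columns=table.data.columns))
            df = pd.DataFrame(out / sums[:, None], index=table.data.index,
                              columns=table.data.columns)
            return AbundanceTable(df, is_normalized=True)
        logger.info("permutation left %d all-zero rows; redrawing "
                    "(attempt %d)", int((sums == 0).sum()), attempt + 1)
    raise RuntimeError(f"could not draw an all-zero-free permutation in "
                       f"{_MAX_REDRAWS} attempts")


def mcnemar_exact(n_discordant_10: int, n_discordant_01: int) -> float:
    """Exact two-sided McNemar p-value from the two discordant counts.

    p = min(1, 2 * P(B <= min(b, c))) with B ~ Binomial(b + c, 1/2). With no
    discordant pairs the test carries no information and p = 1.
    """
    b, c = int(n_discordant_10), int(n_discordant_01)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        logger.warning("no discordant pairs; McNemar p = 1")
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), b + c, 0.5)))


def _well_predicted_flags(X: AbundanceTable, Y: AbundanceTable,
                          config: TrainConfig,
                          policy: FilterPolicy) -> pd.Series:
    model = train_all(X, Y, config, policy)
    return model.well_predicted


def run_null(X: AbundanceTable, Y: AbundanceTable, config: TrainConfig,
             policy: FilterPolicy | None = None, n_iterations: int = 20,
             seed: int = 0, mode: str = "per-feature") -> NullRunSummary:
    """Estimate the null distribution of the well-predicted fraction.

    Each iteration independently permutes X and Y (fresh child seeds from
    the master seed), retrains every metabolite model, and records the
    fraction flagged well predicted. The observed (unshuffled) fraction and
    the exact McNemar comparison between the true flags and the first
    permuted run's flags are returned alongside. The iteration count is a
    runtime knob; the procedure itself does not change with it.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    policy = policy or FilterPolicy()
    Xn = tss_normalize(X) if not X.is_normalized else X
    Yn = tss_normalize(Y) if not Y.is_normalized else Y

    observed = _well_predicted_flags(Xn, Yn, config, policy)
    observed_fraction = float(observed.mean())

    master = np.random.default_rng(seed)
    fractions = np.empty(n_iterations)
    first_null_flags: pd.Series | None = None
    for i in range(n_iterations):
        sx, sy = master.integers(0, 2**31 - 1, size=2)
        Xp = permute_and_renormalize(Xn, sx, mode=mode)
        Yp = permute_and_renormalize(Yn, sy, mode=mode)
        flags = _well_predicted_flags(Xp, Yp, config, policy)
        fractions[i] = float(flags.mean())
        if i == 0:
            first_null_flags = flags

    # paired per-metabolite comparison; metabolites filtered out of either
    # run count as not well predicted there
    mets = observed.index.union(first_null_flags.index)
    obs = observed.reindex(mets, fill_value=False).astype(bool)
    nul = first_null_flags.reindex(mets, fill_value=False).astype(bool)
    p = mcnemar_exact(int((obs & ~nul).sum()), int((~obs & nul).sum()))

    return NullRunSummary(n_iterations=n_iterations, null_fractions=fractions,
                          observed_fraction=observed_fraction,
                          mcnemar_p=p, seed=seed)
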