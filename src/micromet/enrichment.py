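"""Feature-usage ranking and gene-set enrichment.

Predictor features are ranked by how many well-predicted metabolite models
use them (nonzero coefficient). Gene sets are tested two ways: a classic
unweighted KS running-sum enrichment score with a permutation p-value
(random placements of the set members within the fixed ranking), and a
one-tailed Fisher over-representation test of set membership among the
candidate (ever-used) features. Both are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import GeneSetCollection, WeightMatrix


@dataclass
class RankedFeatureList:
    """Features ordered by model usage (descending, lexicographic ties)."""

    feature_ids: list[str]
    usage_scores: np.ndarray  # aligned with feature_ids, non-increasing


@dataclass
class EnrichmentResult:
    """KS enrichment of one gene set within the ranked feature list."""

    set_name: str
    es: float
    p: float
    q: float | None
    direction: str  # "over" (top of list) or "under" (bottom)
    set_size: int


def rank_features_by_usage(model: WeightMatrix) -> RankedFeatureList:
    """Count, per feature, the well-predicted models using it; sort.

    Ties are broken lexicographically by feature id so the ranking is
    deterministic.
    """
    wp = model.well_predicted.astype(bool)
    if not wp.any():
        raise ValueError("no well-predicted metabolites; nothing to rank")
    usage = (model.coefficients.loc[:, wp.to_numpy()] != 0).sum(axis=1)
    order = sorted(usage.index, key=lambda f: (-usage[f], f))
    return RankedFeatureList(feature_ids=order,
                             usage_scores=usage.loc[order].to_numpy())


def _ks_from_positions(positions: np.ndarray, n_total: int,
                       n_members: int) -> np.ndarray:
    """Signed extreme deviation of the KS running sum, vectorized.

    positions: (n_rows, n_members) sorted 0-based member positions. The
    running sum gains 1/n_members at each member and loses
    1/(n_total - n_members) elsewhere; local maxima sit just after a member,
    local minima just before one (and at the start, value 0).
    """
    inc = 1.0 / n_members
    dec = 1.0 / (n_total - n_members)
    i = np.arange(1, n_members + 1)
    at_member = i * inc - (positions + 1 - i) * dec
    before_member = (i - 1) * inc - (positions + 1 - i) * dec
    hi = at_member.max(axis=-1)
    lo = np.minimum(before_member.min(axis=-1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def ks_enrichment(ranked: RankedFeatureList, gene_set: list[str],
                  set_name: str = "", n_permutations: int = 100_000,
                  seed: int = 0) -> EnrichmentResult:
    """Unweighted KS enrichment score with a permutation p-value.

    The null randomizes the member positions within the fixed ranking; the
    p-value is the smoothed fraction of permutations whose |ES| reaches the
    observed |ES|: (1 + hits) / (n_permutations + 1), so p > 0 always.
    """
    n = len(ranked.feature_ids)
    members = set(gene_set) & set(ranked.feature_ids)
    if not members:
        raise ValueError(f"gene set {set_name or '<unnamed>'} shares no "
                         "features with the ranked list")
    h = len(members)
    if h == n:
        return EnrichmentResult(set_name=set_name, es=0.0, p=1.0, q=None,
                                direction="over", set_size=h)
    pos = np.sort([i for i, f in enumerate(ranked.feature_ids)
                   if f in members])
    es = float(_ks_from_positions(pos[None, :], n, h)[0])

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_permutations, 20_000))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        keys = rng.random((m, n))
        perm_pos = np.sort(np.argpartition(keys, h - 1, axis=1)[:, :h],
                           axis=1)
        null_es = _ks_from_positions(perm_pos, n, h)
        hits += int((np.abs(null_es) >= abs(es) - 1e-12).sum())
        done += m
    p = (1 + hits) / (n_permutations + 1)
    return EnrichmentResult(set_name=set_name, es=es, p=float(p), q=None,
                            direction="over" if es >= 0 else "under",
                            set_size=h)


def fisher_overrepresentation(in_set_candidate: int, in_set_rest: int,
                              out_set_candidate: int,
                              out_set_rest: int) -> float:
    """One-tailed (greater) Fisher exact p for candidate over-representation.

    The 2x2 table crosses set membership with candidate status; the p-value
    is the hypergeometric tail P(X >= in_set_candidate) at fixed margins.
    """
    table = np.array([[in_set_candidate, in_set_rest],
                      [out_set_candidate, out_set_rest]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("empty 2x2 table")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_enrichment(model: WeightMatrix, collection: GeneSetCollection,
                   n_permutations: int = 100_000, seed: int = 0,
                   q_threshold: float = 0.25) -> pd.DataFrame:
    """KS enrichment plus Fisher over-representation for every gene set.

    Candidates for the Fisher test are the features used by at least one
    well-predicted model. Both p-value families are BH-corrected
    independently; ``significant`` marks KS q-values below ``q_threshold``
    (the conventional GSEA reporting cut).
    """
    ranked = rank_features_by_usage(model)
    universe = set(ranked.feature_ids)
    candidates = {f for f, s in zip(ranked.feature_ids, ranked.usage_scores)
                  if s > 0}
    rng = np.random.default_rng(seed)

    rows = []
    for name in collection:
        members = set(collection[name]) & universe
        if not members:
            continue
        res = ks_enrichment(ranked, sorted(members), set_name=name,
                            n_permutations=n_permutations,
                            seed=int(rng.integers(0, 2**31 - 1)))
        a = len(members & candidates)
        b = len(members - candidates)
        c = len(candidates - members)
        d = len(universe - candidates - members)
        fisher_p = fisher_overrepresentation(a, b, c, d)
        rows.append({"set_name": name, "set_size": res.set_size,
                     "es": res.es, "direction": res.direction, "p": res.p,
                     "fisher_p": fisher_p})
    if not rows:
        raise ValueError("no gene set overlaps the model's feature universe")
    out = pd.DataFrame(rows).set_index("set_name")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["fisher_q"] = bh_fdr(out["fisher_p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out
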