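"""Feature-usage ranking, KS enrichment, Fisher, and BH FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from micromet import (GeneSetCollection, RankedFeatureList, WeightMatrix,
                      bh_fdr, fisher_overrepresentation, ks_enrichment,
                      rank_features_by_usage, run_enrichment)
from micromet.enrichment import _ks_from_positions


def _ranked(ids):
    return RankedFeatureList(feature_ids=list(ids),
                             usage_scores=np.arange(len(ids), 0, -1))


def exhaustive_ks_p(n, members_positions):
    """Exact two-sided permutation p by enumerating every placement."""
    h = len(members_positions)
    obs = abs(_ks_from_positions(np.array([sorted(members_positions)]),
                                 n, h)[0])
    hits = total = 0
    for comb_pos in itertools.combinations(range(n), h):
        es = _ks_from_positions(np.array([comb_pos]), n, h)[0]
        hits += abs(es) >= obs - 1e-12
        total += 1
    return hits / total


class TestRankFeaturesByUsage:
    def _model(self):
        coef = pd.DataFrame(
            {"m1": [1.0, 0.0, 2.0, 0.0], "m2": [0.5, 0.0, 0.0, 0.0],
             "m3": [0.0, 3.0, 1.0, 0.0], "m4": [0.0, 0.0, 0.0, 1.0]},
            index=["fa", "fb", "fc", "fd"])
        mets = coef.columns
        return WeightMatrix(
            coefficients=coef,
            intercepts=pd.Series(0.1, index=mets),
            alpha=pd.Series(0.5, index=mets),
            lam=pd.Series(0.1, index=mets),
            cv_spearman=pd.Series([0.8, 0.5, 0.6, 0.1], index=mets),
            well_predicted=pd.Series([True, True, True, False], index=mets))

    def test_counts_only_well_predicted_models(self):
        ranked = self._model()
        out = rank_features_by_usage(ranked)
        scores = dict(zip(out.feature_ids, out.usage_scores))
        # fd appears only in the poorly predicted m4
        assert scores == {"fa": 2, "fc": 2, "fb": 1, "fd": 0}
        assert out.feature_ids == ["fa", "fc", "fb", "fd"]  # lexicographic tie

    def test_no_well_predicted_is_an_error(self):
        m = self._model()
        m.well_predicted[:] = False
        with pytest.raises(ValueError, match="no well-predicted"):
            rank_features_by_usage(m)


class TestKSEnrichment:
    def test_top_two_of_four(self):
        res = ks_enrichment(_ranked("abcd"), ["a", "b"], set_name="top",
                            n_permutations=3000, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.direction == "over"
        # exhaustive two-sided p: both extreme placements reach |es| = 1
        exact = exhaustive_ks_p(4, [0, 1])
        assert exact == pytest.approx(2 / 6)
        se = np.sqrt(exact * (1 - exact) / 3000)
        assert abs(res.p - exact) < 3 * se + 1 / 3001

    def test_set_covering_whole_list_is_degenerate(self):
        res = ks_enrichment(_ranked("abc"), ["a", "b", "c"],
                            n_permutations=10, seed=0)
        assert res.es == 0.0 and res.p == 1.0

    def test_bottom_set_signed_negative(self):
        res = ks_enrichment(_ranked("abcdef"), ["e", "f"],
                            n_permutations=2000, seed=1)
        assert res.es < 0
        assert res.direction == "under"

    @pytest.mark.parametrize("n,members", [
        (6, (0, 3)), (8, (1, 2, 7)), (7, (4, 5, 6)), (8, (0,)),
    ])
    def test_matches_exhaustive_enumeration(self, n, members):
        ids = [chr(97 + i) for i in range(n)]
        gene_set = [ids[i] for i in members]
        res = ks_enrichment(_ranked(ids), gene_set, n_permutations=4000,
                            seed=3)
        exact = exhaustive_ks_p(n, list(members))
        se = np.sqrt(max(exact * (1 - exact), 1e-9) / 4000)
        assert abs(res.p - exact) <= 3 * se + 1 / 4001

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(ValueError, match="no.*features|shares no"):
            ks_enrichment(_ranked("abc"), ["zzz"], set_name="zset")

    def test_p_values_uniform_under_random_sets(self):
        # the permutation p must be valid (never anti-conservative beyond
        # Monte-Carlo error) and close to uniform; ties in the discrete null
        # make it mildly conservative in the middle of the range
        rng = np.random.default_rng(4)
        ids = [f"f{i}" for i in range(40)]
        ps = []
        for _ in range(200):
            members = rng.choice(ids, size=5, replace=False).tolist()
            ps.append(ks_enrichment(_ranked(ids), members,
                                    n_permutations=2000,
                                    seed=int(rng.integers(2**31))).p)
        ps = np.asarray(ps)
        for t in (0.05, 0.10, 0.25, 0.50):
            se = np.sqrt(t * (1 - t) / 200)
            assert (ps <= t).mean() <= t + 3 * se
            assert (ps <= t).mean() >= t - 4 * se


class TestFisher:
    def test_closed_forms(self):
        assert fisher_overrepresentation(1, 0, 0, 1) == pytest.approx(0.5)
        assert fisher_overrepresentation(5, 0, 0, 5) == pytest.approx(
            1 / comb(10, 5, exact=True))
        assert fisher_overrepresentation(0, 3, 4, 5) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self):
        # exact hypergeometric tail by enumerating the support
        from math import comb as C
        for a, b, c, d in [(2, 1, 3, 4), (3, 2, 1, 5), (1, 1, 1, 1)]:
            n, row1, col1 = a + b + c + d, a + b, a + c
            tail = sum(C(col1, k) * C(n - col1, row1 - k)
                       for k in range(a, min(row1, col1) + 1)) / C(n, row1)
            assert fisher_overrepresentation(a, b, c, d) == pytest.approx(
                tail, rel=1e-12)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_overrepresentation(0, 0, 0, 0)


class TestBHFDR:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_statsmodels_and_is_monotone(self, ps):
        q = bh_fdr(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRunEnrichment:
    def test_table_shape_and_flags(self):
        rng = np.random.default_rng(5)
        ids = [f"f{i}" for i in range(30)]
        coef = pd.DataFrame(rng.standard_normal((30, 4))
                            * (rng.random((30, 4)) < 0.4),
                            index=ids, columns=["m1", "m2", "m3", "m4"])
        mets = coef.columns
        model = WeightMatrix(
            coefficients=coef, intercepts=pd.Series(0.1, index=mets),
            alpha=pd.Series(0.5, index=mets), lam=pd.Series(0.1, index=mets),
            cv_spearman=pd.Series([0.5, 0.4, 0.2, 0.6], index=mets),
            well_predicted=pd.Series([True, True, False, True], index=mets))
        sets = GeneSetCollection({"s1": ids[:6], "s2": ids[10:14],
                                  "s3": ["nothere"]})
        out = run_enrichment(model, sets, n_permutations=500, seed=5)
        assert set(out.index) == {"s1", "s2"}  # s3 has no overlap
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()
        assert (out["q"] >= out["p"] - 1e-12).all()
        assert {"es", "direction", "fisher_p", "fisher_q",
                "significant"} <= set(out.columns)
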