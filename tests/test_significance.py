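"""Permutation null, empirical p-values, BH-FDR and candidate selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seedwalk.network import _from_edges
from seedwalk.rwr import RWRConfig, make_seed_vector, run_rwr
from seedwalk.significance import (
    _pseudo_seed_sets,
    bh_fdr,
    candidate_table,
    empirical_pvalues,
    observed_candidate_scores,
    permutation_null,
    select_candidates,
)
from .conftest import make_network


def toy6():
    """3 miRNAs x 3 genes, connected, heterogeneous degrees."""
    return make_network(
        [("m1", "g1"), ("m1", "g2"), ("m2", "g2"), ("m2", "g3"), ("m3", "g3")]
    )


class TestPermutationNull:
    def test_reproducible_given_rng_seed(self):
        net = toy6()
        a, cand_a = permutation_null(net, ["m1"], n_perm=20, rng_seed=42)
        b, cand_b = permutation_null(net, ["m1"], n_perm=20, rng_seed=42)
        assert cand_a == cand_b
        np.testing.assert_array_equal(a, b)

    def test_pseudo_seed_equal_to_true_seed_reproduces_observed(self):
        # the permutation drawing the true seed set yields the observed scores
        net = toy6()
        cfg = RWRConfig(tol=1e-10)
        observed = run_rwr(net, make_seed_vector(net, ["m1"]), cfg)
        null, candidates = permutation_null(net, ["m1"], n_perm=30,
                                            rng_seed=0, config=cfg)
        sets = _pseudo_seed_sets(net, ["m1"], 30,
                                 np.random.default_rng(0), "uniform")
        rows = [b for b, s in enumerate(sets) if s == [net.node_index["m1"]]]
        assert rows, "rng never drew the true seed in 30 tries"
        obs = observed_candidate_scores(net, observed, candidates)
        np.testing.assert_allclose(null[rows[0]], obs, atol=1e-9)

    def test_column_means_match_exhaustive_enumeration(self):
        # exhaustive average over all single-miRNA pseudo-seed choices
        net = toy6()
        cfg = RWRConfig(tol=1e-12)
        null, candidates = permutation_null(net, ["m1"], n_perm=50,
                                            rng_seed=7, config=cfg)
        idx = net.node_index
        by_seed = {
            m: run_rwr(net, make_seed_vector(net, [m]), cfg).values
            for m in net.mirna_nodes
        }
        for j, cand in enumerate(candidates):
            exact = np.mean(
                [by_seed[m][idx[cand]] for m in net.mirna_nodes if m != cand]
            )
            col = null[:, j]
            col = col[~np.isnan(col)]
            se = col.std(ddof=1) / np.sqrt(len(col))
            assert abs(col.mean() - exact) <= 3 * se + 1e-12

    def test_candidate_self_seed_entries_masked(self):
        net = toy6()
        null, candidates = permutation_null(net, ["m1"], n_perm=200, rng_seed=1)
        # with 1 pseudo-seed among 3 miRNAs, each candidate is drawn ~1/3
        nan_frac = np.isnan(null).mean(axis=0)
        assert np.all(nan_frac > 0.1) and np.all(nan_frac < 0.6)

    def test_too_many_seeds_rejected(self):
        net = toy6()
        with pytest.raises(ValueError):
            _pseudo_seed_sets(net, ["m1", "m2", "m3", "m4"], 1,
                              np.random.default_rng(0), "uniform")

    def test_degree_matched_sets_track_seed_degrees(self):
        net = toy6()
        sets = _pseudo_seed_sets(net, ["m2"], 50,
                                 np.random.default_rng(0), "degree_matched")
        assert all(len(s) == 1 for s in sets)


class TestEmpiricalPvalues:
    def test_observed_above_all_nulls(self):
        null = np.arange(9, dtype=float).reshape(9, 1)
        assert empirical_pvalues(np.array([100.0]), null)[0] == pytest.approx(0.1)

    def test_observed_below_all_nulls(self):
        null = np.arange(1, 10, dtype=float).reshape(9, 1)
        assert empirical_pvalues(np.array([0.0]), null)[0] == pytest.approx(1.0)

    def test_ties_count_as_exceeding(self):
        # 4 of 9 null values tie the observed, the rest lie below
        null = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 5.0, 5.0, 5.0]).reshape(9, 1)
        p = empirical_pvalues(np.array([5.0]), null)[0]
        assert p == pytest.approx(5 / 10)

    def test_nan_entries_shrink_b(self):
        null = np.array([[1.0], [np.nan], [3.0]])
        p = empirical_pvalues(np.array([2.0]), null)[0]
        assert p == pytest.approx((1 + 1) / 3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            empirical_pvalues(np.array([1.0, 2.0]), np.zeros((5, 3)))


class TestBHFDR:
    def test_worked_step_up_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.04, 0.05]), [0.04, 0.04, 0.05, 0.05]
        )

    def test_all_ties_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.03] * 5), [0.03] * 5)

    def test_single_p_identity(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_q_monotone_in_sorted_p_order(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))


class TestSelection:
    def test_strict_inequality_at_alpha(self):
        table = pd.DataFrame(
            {"mirna_id": ["a", "b", "c"], "score": [3.0, 2.0, 1.0],
             "emp_p": [0.01, 0.04, 0.05], "q_value": [0.01, 0.049, 0.05]}
        )
        out = select_candidates(table, alpha=0.05)
        assert list(out["selected"]) == [True, True, False]

    def test_alpha_one_selects_all(self):
        table = pd.DataFrame(
            {"mirna_id": ["a"], "score": [1.0], "emp_p": [0.9], "q_value": [0.9]}
        )
        assert select_candidates(table, alpha=1.0)["selected"].all()

    def test_empty_table_passthrough(self):
        table = pd.DataFrame(
            columns=["mirna_id", "score", "emp_p", "q_value"]
        )
        assert len(select_candidates(table)) == 0

    def test_candidate_table_sorted_by_score(self):
        net = toy6()
        cfg = RWRConfig(tol=1e-10)
        scores = run_rwr(net, make_seed_vector(net, ["m1"]), cfg)
        null, candidates = permutation_null(net, ["m1"], n_perm=30,
                                            rng_seed=0, config=cfg)
        obs = observed_candidate_scores(net, scores, candidates)
        tab = candidate_table(candidates, obs, null)
        assert set(tab["mirna_id"]) == {"m2", "m3"}
        assert list(tab["score"]) == sorted(tab["score"], reverse=True)
        assert ((tab["emp_p"] > 0) & (tab["emp_p"] <= 1)).all()

    def test_doubling_b_changes_p_within_noise(self):
        net = toy6()
        cfg = RWRConfig(tol=1e-10)
        scores = run_rwr(net, make_seed_vector(net, ["m1"]), cfg)
        null, candidates = permutation_null(net, ["m1"], n_perm=400,
                                            rng_seed=3, config=cfg)
        obs = observed_candidate_scores(net, scores, candidates)
        p_half = empirical_pvalues(obs, null[:200])
        p_full = empirical_pvalues(obs, null)
        bound = 3 * np.sqrt(0.25 / 200) + 1 / 201
        assert np.all(np.abs(p_full - p_half) <= bound)
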