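import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import devvar as dv

from conftest import make_matrix, make_samples


class TestTopVarianceSubset:
    def test_fraction_one_keeps_all(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 5)))
        assert set(dv.top_variance_subset(m, 1.0)) == set(m.probe_ids)

    def test_boundary_ties_break_lexicographically(self):
        # exact variances 10, 5, 5, 1 via a scaled base row
        base = np.array([-1.0, 0.0, 1.0])  # var 1
        values = np.vstack(
            [base * np.sqrt(10), base * np.sqrt(5), base * np.sqrt(5), base]
        )
        m = make_matrix(values, probe_ids=["Pc", "Pb", "Pa", "Pz"])
        assert dv.top_variance_subset(m, 0.5) == ["Pc", "Pa"]

    def test_explicit_k_override(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 5)))
        assert len(dv.top_variance_subset(m, k=3)) == 3

    def test_constant_matrix_errors(self):
        m = make_matrix(np.ones((3, 4)))
        with pytest.raises(ValueError, match="constant"):
            dv.top_variance_subset(m, 0.5)


class TestVarianceRatioFTest:
    def test_identical_groups_give_f1_p_half(self):
        vals = np.array([[0.0, 1, 2, 0, 1, 2]])
        m = make_matrix(vals)
        s = make_samples([1, 2, 3, 20, 30, 40])
        res = dv.variance_ratio_ftest(m, s)
        assert res["F"].iloc[0] == pytest.approx(1.0)
        assert res["p_one_sided"].iloc[0] == pytest.approx(0.5)

    def test_closed_form_f22(self):
        # young var 4, old var 1 -> F=4 with df (2,2); upper tail 1/(1+4)
        m = make_matrix([[0.0, 2, 4, 0, 1, 2]])
        s = make_samples([1, 2, 3, 20, 30, 40])
        res = dv.variance_ratio_ftest(m, s)
        row = res.iloc[0]
        assert (row["df_num"], row["df_den"]) == (2, 2)
        assert row["F"] == pytest.approx(4.0)
        assert row["p_one_sided"] == pytest.approx(0.2)
        assert row["sd_young"] == pytest.approx(2.0)
        assert row["sd_old"] == pytest.approx(1.0)

    def test_degenerate_variance_conventions(self):
        m = make_matrix([[0.0, 2, 4, 1, 1, 1], [1.0, 1, 1, 1, 1, 1]])
        s = make_samples([1, 2, 3, 20, 30, 40])
        res = dv.variance_ratio_ftest(m, s)
        assert res["p_one_sided"].iloc[0] == 0.0
        assert res["p_one_sided"].iloc[1] == 1.0
        assert res["degenerate"].all()

    def test_mc_tail_frequency_matches_p(self):
        # p-value equals the Monte-Carlo tail frequency of the variance
        # ratio under a shared-normal null at n=(29, 8)
        rng = np.random.default_rng(5)
        B = 200_000
        s2y = rng.chisquare(28, B) / 28
        s2o = rng.chisquare(7, B) / 7
        ratios = s2y / s2o
        for x in (1.5, 3.0, 6.0):
            mc = (ratios >= x).mean()
            p = stats.f.sf(x, 28, 7)
            se = np.sqrt(p * (1 - p) / B)
            assert abs(mc - p) < 3 * se + 1e-4

    def test_reciprocal_f_relation_on_label_swap(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 12))
        m = make_matrix(vals)
        ages = [1] * 7 + [20] * 5
        s = make_samples(ages)
        s_swapped = make_samples([20] * 7 + [1] * 5)
        p = dv.variance_ratio_ftest(m, s)["p_one_sided"].to_numpy()
        p_swap = dv.variance_ratio_ftest(m, s_swapped)["p_one_sided"].to_numpy()
        np.testing.assert_allclose(p_swap, 1.0 - p, atol=1e-12)


class TestAdjustFdr:
    def test_bh_step_up_hand_example(self):
        q = dv.adjust_fdr([0.01, 0.02, 0.03, 0.04], method="bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged_under_bh(self):
        assert dv.adjust_fdr([0.3], method="bh")[0] == pytest.approx(0.3)

    def test_storey_with_fixed_lambda_hand_example(self):
        p = [0.01, 0.02, 0.6, 0.8]
        assert dv.estimate_pi0(np.array(p), lambda_=0.5) == pytest.approx(1.0)
        q = dv.adjust_fdr(p, method="storey", lambda_=0.5)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.8, 0.8])

    def test_empty_list(self):
        assert len(dv.adjust_fdr([], method="bh")) == 0

    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=40))
    def test_bh_q_at_least_p_and_monotone(self, p):
        q = dv.adjust_fdr(p, method="bh")
        p = np.asarray(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=1, max_size=30),
        st.sampled_from([0.05, 0.1, 0.25]),
    )
    def test_bh_threshold_reproduces_step_up_rejections(self, p, alpha):
        p = np.asarray(p)
        q = dv.adjust_fdr(p, method="bh")
        m = len(p)
        # independent step-up oracle
        order = np.argsort(p)
        ks = [i + 1 for i in range(m) if p[order[i]] <= (i + 1) * alpha / m]
        reject_oracle = np.zeros(m, bool)
        if ks:
            reject_oracle[order[: max(ks)]] = True
        np.testing.assert_array_equal(q <= alpha, reject_oracle)

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(0, 0.01, 50), rng.uniform(0, 1, 200)])
        q_bh = dv.adjust_fdr(p, "bh")
        q_st = dv.adjust_fdr(p, "storey")
        assert (q_st <= q_bh + 1e-12).all()


def _enumerate_signed_rank_p(diffs):
    """Exact one-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if w >= w_obs:
            count += 1
    return count / 2**n


class TestSignedRank:
    def test_three_positive_differences(self):
        assert dv.signed_rank_paired_sd([1, 2, 3], [0, 0, 0]) == pytest.approx(0.125)

    def test_all_zero_differences(self):
        assert dv.signed_rank_paired_sd([1, 2], [1, 2]) == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        d = rng.normal(size=n)
        p = dv.signed_rank_paired_sd(d, np.zeros(n))
        assert p == pytest.approx(_enumerate_signed_rank_p(d), abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 1.0, size=60)
        p = dv.signed_rank_paired_sd(d, np.zeros(60))
        assert 0 < p < 1


class TestProportionGreater:
    def test_identical_lists_give_zero(self):
        assert dv.proportion_sd_greater([1, 2], [1, 2]) == 0.0

    def test_direct_count(self):
        assert dv.proportion_sd_greater([2, 1, 3], [1, 2, 1]) == pytest.approx(2 / 3)


class TestPermutationNull:
    def test_zero_permutations_rejected(self, processed_study):
        matrix, samples, _ = processed_study
        with pytest.raises(ValueError, match="n_perm"):
            dv.permutation_null_proportion(matrix, samples, n_perm=0)

    def test_returns_null_sample_and_empirical_p(self, processed_study):
        matrix, samples, _ = processed_study
        res = dv.permutation_null_proportion(
            matrix, samples, fraction=0.2, n_perm=30, seed=4
        )
        assert len(res.null_proportions) == 30
        assert 0 < res.p_empirical <= 1
        assert 0 <= res.observed <= 1


class TestScreen:
    def test_qvalues_only_within_selected_subset(self, processed_study):
        matrix, samples, _ = processed_study
        res = dv.run_variance_screen(matrix, samples, fraction=0.1)
        sel = res["selected_top_variance"]
        assert res.loc[sel, "q_pfdr"].notna().all()
        assert res.loc[~sel, "q_pfdr"].isna().all()
        assert not (res["significant"] & ~sel).any()

    def test_recovers_planted_dv_genes(self, processed_study):
        matrix, samples, truth = processed_study
        res = dv.run_variance_screen(matrix, samples, fraction=1.0)
        flagged = set(res.index[res["significant"]])
        dv_probes = set(truth.probes_of_class("dv")) & set(res.index)
        power = len(flagged & dv_probes) / len(dv_probes)
        assert power > 0.5
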