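import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import survscreen as ss
from survscreen.diffexp import ModerationParams


def matrix_from(arr, prefix="G"):
    arr = np.asarray(arr, dtype=float)
    return ss.ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"{prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"S{j}" for j in range(arr.shape[1])],
        )
    )


class TestQuantileNormalize:
    def test_two_column_rank_means(self):
        m = matrix_from(np.array([[1, 2], [3, 4], [5, 6]]))
        out = ss.quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [1.5, 3.5, 5.5])
        np.testing.assert_allclose(out[:, 1], [1.5, 3.5, 5.5])

    def test_identical_columns_fixed_point(self):
        col = np.array([2.0, 7.0, 4.0, 9.0])
        m = matrix_from(np.column_stack([col, col, col]))
        np.testing.assert_allclose(ss.quantile_normalize(m).values.to_numpy(), m.values.to_numpy())

    def test_column_means_equal_after(self, tiny_matrix):
        out = ss.quantile_normalize(tiny_matrix).values.to_numpy()
        means = out.mean(axis=0)
        np.testing.assert_allclose(means, means[0], atol=1e-12)

    def test_idempotent(self, tiny_matrix):
        once = ss.quantile_normalize(tiny_matrix)
        twice = ss.quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10)

    def test_ties_get_mean_of_spanned_values(self):
        m = matrix_from(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
        out = ss.quantile_normalize(m).values.to_numpy()
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        np.testing.assert_allclose(out[:2, 0], (ref[0] + ref[1]) / 2)

    def test_missing_cells_restored(self):
        arr = np.array([[1.0, 2.0], [np.nan, 4.0], [5.0, 6.0]])
        out = ss.quantile_normalize(matrix_from(arr)).values.to_numpy()
        assert np.isnan(out[1, 0]) and np.isfinite(out[[0, 2], 0]).all()

    def test_single_sample_returned_unchanged(self):
        m = matrix_from(np.array([[1.0], [2.0]]))
        np.testing.assert_array_equal(ss.quantile_normalize(m).values, m.values)


class TestEstimateModeration:
    def test_recovers_scaled_f_hyperparameters(self):
        rng = np.random.default_rng(11)
        d0, s0_sq, df, n = 4.0, 0.05, 52, 20000
        s2 = s0_sq * (stats.chi2.rvs(df, size=n, random_state=rng) / df) / (
            stats.chi2.rvs(d0, size=n, random_state=rng) / d0
        )
        est = ss.estimate_moderation(s2, df)
        assert est.d0 == pytest.approx(d0, rel=0.15)
        assert est.s0_sq == pytest.approx(s0_sq, rel=0.15)

    def test_identical_variances_give_infinite_d0(self):
        est = ss.estimate_moderation(np.full(100, 0.3), residual_df=10)
        assert np.isinf(est.d0)

    def test_few_probes_fall_back_to_no_moderation(self):
        est = ss.estimate_moderation(np.linspace(0.1, 1, 10), residual_df=10)
        assert est.d0 == 0.0

    def test_heavy_tailed_contamination_stays_finite(self):
        rng = np.random.default_rng(12)
        s2 = np.concatenate([rng.chisquare(5, 5000) / 5, rng.pareto(1.2, 500) + 0.5])
        est = ss.estimate_moderation(s2, residual_df=5)
        assert 0 < est.d0 < np.inf and est.s0_sq > 0


class TestModeratedT:
    def test_d0_zero_equals_classical_pooled_t(self, tiny_matrix):
        low, high = tiny_matrix.sample_ids[:6], tiny_matrix.sample_ids[6:]
        rec = ss.moderated_t_test(tiny_matrix, low, high, ModerationParams(0.0, 1.0))
        X = tiny_matrix.values
        t_ref, p_ref = stats.ttest_ind(X[high], X[low], axis=1, equal_var=True)
        np.testing.assert_allclose(rec["t_moderated"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(rec["p_value"], p_ref, rtol=1e-10)

    def test_infinite_d0_uses_prior_variance_everywhere(self, tiny_matrix):
        low, high = tiny_matrix.sample_ids[:6], tiny_matrix.sample_ids[6:]
        rec = ss.moderated_t_test(tiny_matrix, low, high, ModerationParams(np.inf, 0.25))
        np.testing.assert_allclose(rec["posterior_s2"], 0.25)

    def test_log2fc_is_high_minus_low(self, tiny_matrix):
        low, high = tiny_matrix.sample_ids[:6], tiny_matrix.sample_ids[6:]
        rec = ss.moderated_t_test(tiny_matrix, low, high)
        np.testing.assert_allclose(rec["log2fc"], rec["mean_high"] - rec["mean_low"], atol=1e-14)

    def test_shrinkage_pulls_variances_toward_prior(self, tiny_matrix):
        low, high = tiny_matrix.sample_ids[:6], tiny_matrix.sample_ids[6:]
        strong = ss.moderated_t_test(tiny_matrix, low, high, ModerationParams(50.0, 1.0))
        weak = ss.moderated_t_test(tiny_matrix, low, high, ModerationParams(0.5, 1.0))
        assert strong["posterior_s2"].std() < weak["posterior_s2"].std()


def brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based ascending rank
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return np.minimum(adj, 1.0)


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(ss.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(ss.bh_adjust([0.03]), [0.03])

    def test_empty_input(self):
        assert ss.bh_adjust([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_equals_brute_force_step_up(self, p):
        np.testing.assert_allclose(ss.bh_adjust(p), brute_force_bh(np.array(p)), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_input_and_capped_at_one(self, p):
        adj = ss.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1.0).all()


class TestSelectDEGenes:
    @pytest.mark.parametrize(
        "log2fc,q,fc_cut,expect_up",
        [(1.2, 0.01, 1.0, True), (1.2, 0.01, 1.5, False), (1.2, 0.2, 1.0, False)],
    )
    def test_threshold_rules(self, log2fc, q, fc_cut, expect_up):
        rec = pd.DataFrame({"log2fc": [log2fc], "p_adjusted": [q]}, index=["G1"])
        up, down = ss.select_de_genes(rec, fc_cut=fc_cut)
        assert (("G1" in up) == expect_up) and down == []

    def test_down_side_is_symmetric(self):
        rec = pd.DataFrame({"log2fc": [-2.0], "p_adjusted": [0.001]}, index=["G1"])
        up, down = ss.select_de_genes(rec)
        assert up == [] and down == ["G1"]


class TestFDRCalibration:
    def test_global_null_keeps_discoveries_at_bay(self):
        rng = np.random.default_rng(13)
        m = matrix_from(rng.normal(0, 1, size=(2000, 20)))
        rec = ss.moderated_t_test(m, m.sample_ids[:10], m.sample_ids[10:])
        assert (rec["p_adjusted"] < 0.05).mean() <= 0.05
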