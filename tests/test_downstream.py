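import numpy as np
import pandas as pd
import pytest

import survscreen as ss


def matrix_from(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    return ss.ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=genes or [f"G{i}" for i in range(arr.shape[0])],
            columns=samples or [f"S{j}" for j in range(arr.shape[1])],
        )
    )


class TestPatientCluster:
    def test_identical_pair_merges_first_at_height_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=5)
        m = matrix_from(np.column_stack([base, base, rng.normal(size=5)]))
        dendro, corr = ss.patient_cluster(m)
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_planted_two_group_structure_recovered(self):
        rng = np.random.default_rng(7)
        n_genes, per_group = 40, 15
        shift = np.r_[np.full(20, 2.0), np.full(20, -2.0)]
        a = rng.normal(0, 1, (n_genes, per_group)) + shift[:, None]
        b = rng.normal(0, 1, (n_genes, per_group)) - shift[:, None]
        m = matrix_from(np.hstack([a, b]))
        dendro, _ = ss.patient_cluster(m)
        labels = dendro.cut(2)
        truth = np.array([0] * per_group + [1] * per_group)
        pred = np.array([labels[s] for s in m.sample_ids]) - 1
        agreement = max(np.mean(pred == truth), np.mean(pred != truth))
        assert agreement >= 0.9

    def test_merge_heights_non_decreasing(self, tiny_matrix):
        dendro, _ = ss.patient_cluster(tiny_matrix)
        heights = dendro.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_invariant_to_per_sample_affine_rescaling(self, tiny_matrix):
        # correlation distance ignores each sample profile's location/scale
        d1, _ = ss.patient_cluster(tiny_matrix)
        scaled = tiny_matrix.values * 3.0 + 10.0
        d2, _ = ss.patient_cluster(ss.ExpressionMatrix(scaled))
        np.testing.assert_allclose(d1.linkage, d2.linkage, atol=1e-9)

    def test_zero_variance_sample_named_in_error(self):
        m = matrix_from(np.array([[1.0, 5.0, 4.0], [1.0, 2.0, 6.0]]), samples=["A", "B", "C"])
        m.values["A"] = 3.0
        with pytest.raises(ValueError, match="A"):
            ss.patient_cluster(m)

    def test_newick_export_contains_all_leaves(self, tiny_matrix):
        dendro, _ = ss.patient_cluster(tiny_matrix)
        nwk = dendro.to_newick()
        assert nwk.endswith(";") and all(s in nwk for s in tiny_matrix.sample_ids)


class TestGeneZScoreCluster:
    def test_affine_pair_merges_at_zero(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=10)
        m = matrix_from(np.vstack([g, 5 * g + 2, rng.normal(size=10)]))
        dendro = ss.gene_zscore_cluster(m)
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_gene_and_negation_distance(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=12)
        m = matrix_from(np.vstack([g, -g, rng.normal(size=12)]))
        dendro = ss.gene_zscore_cluster(m)
        # z-scored opposite vectors: ||z - (-z)|| = 2 * sqrt(n)
        d = np.linalg.norm((g - g.mean()) / g.std() * 2)
        assert d == pytest.approx(2 * np.sqrt(12))
        merged = dendro.linkage[np.isclose(dendro.linkage[:, 2], d)]
        assert merged.size > 0

    def test_hand_computed_merge_order(self):
        # genes A,B close, C far: z-score-free construction with exact distances
        a = np.array([0.0, 1.0, 2.0, 3.0])
        m = matrix_from(np.vstack([a, a[::-1], np.array([0.0, 3.0, 1.0, 2.0])]),
                        genes=["A", "B", "C"])
        dendro = ss.gene_zscore_cluster(m)
        za = (a - a.mean()) / a.std()
        zb = za[::-1]
        c = np.array([0.0, 3.0, 1.0, 2.0])
        zc = (c - c.mean()) / c.std()
        d_ab = np.linalg.norm(za - zb)
        d_ac = np.linalg.norm(za - zc)
        d_bc = np.linalg.norm(zb - zc)
        first = dendro.linkage[0]
        expected_first = min([(d_ab, {0, 1}), (d_ac, {0, 2}), (d_bc, {1, 2})])[1]
        assert {int(first[0]), int(first[1])} == expected_first

    def test_constant_gene_named_in_error(self):
        m = matrix_from(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]), genes=["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            ss.gene_zscore_cluster(m)


class TestSignalToNoise:
    def test_direct_formula(self):
        rng = np.random.default_rng(3)
        lo = rng.normal(0, 1, (1, 50))
        hi = rng.normal(2, 1, (1, 50))
        m = matrix_from(np.hstack([lo, hi]))
        low, high = m.sample_ids[:50], m.sample_ids[50:]
        s = ss.signal_to_noise_rank(m, low, high)
        m_lo, m_hi = lo.mean(), hi.mean()
        s_lo = max(lo.std(ddof=1), 0.2 * abs(m_lo), 0.2)
        s_hi = max(hi.std(ddof=1), 0.2 * abs(m_hi), 0.2)
        assert s.iloc[0] == pytest.approx((m_hi - m_lo) / (s_hi + s_lo))

    def test_identical_distributions_score_zero(self):
        vals = np.tile(np.arange(6, dtype=float), (3, 1))
        m = matrix_from(np.hstack([vals, vals]))
        s = ss.signal_to_noise_rank(m, m.sample_ids[:6], m.sample_ids[6:])
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_label_swap_negates_and_reverses(self, tiny_matrix):
        low, high = tiny_matrix.sample_ids[:6], tiny_matrix.sample_ids[6:]
        s1 = ss.signal_to_noise_rank(tiny_matrix, low, high)
        s2 = ss.signal_to_noise_rank(tiny_matrix, high, low)
        np.testing.assert_allclose(s1.sort_index(), -s2.sort_index(), atol=1e-12)
        assert list(s1.index) == list(s2.index[::-1])


def brute_force_es(ranked, gene_set):
    """Independent running-sum recomputation of the enrichment score."""
    members = set(gene_set)
    total = sum(abs(v) for g, v in ranked.items() if g in members)
    n_miss = len(ranked) - sum(g in members for g in ranked.index)
    best, run = 0.0, 0.0
    for g, v in ranked.items():
        run += abs(v) / total if g in members else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestEnrichmentScore:
    def test_top_ranked_singleton_scores_one(self):
        ranked = pd.Series([3.0, 2.0, 1.0, 0.5], index=["A", "B", "C", "D"])
        es, running, leading = ss.enrichment_score(ranked, ["A"])
        assert es == pytest.approx(1.0) and leading == ["A"]

    def test_absent_set_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["A", "B"])
        with pytest.raises(ValueError):
            ss.enrichment_score(ranked, ["Z"])

    def test_full_coverage_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["A", "B"])
        with pytest.raises(ValueError):
            ss.enrichment_score(ranked, ["A", "B"])

    def test_matches_brute_force_running_sum(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(10, 60)
            genes = [f"G{i}" for i in range(n)]
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = pd.Series(scores, index=genes)
            members = list(rng.choice(genes, size=rng.integers(1, n // 2 + 1), replace=False))
            es, _, _ = ss.enrichment_score(ranked, members)
            assert es == pytest.approx(brute_force_es(ranked, members), abs=1e-12)

    def test_reversed_negated_ranking_negates_es(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(30)]
        ranked = pd.Series(np.sort(rng.normal(size=30))[::-1], index=genes)
        members = genes[2:8]
        es_fwd, _, _ = ss.enrichment_score(ranked, members)
        es_rev, _, _ = ss.enrichment_score(-ranked[::-1], members)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)


class TestGSEAPermutation:
    def test_deterministic_under_fixed_seed(self, tiny_matrix):
        low, high = tiny_matrix.sample_ids[:6], tiny_matrix.sample_ids[6:]
        r1 = ss.gsea_permutation_p(tiny_matrix, low, high, ["G0", "G1", "G2"], n_perm=100, seed=5)
        r2 = ss.gsea_permutation_p(tiny_matrix, low, high, ["G0", "G1", "G2"], n_perm=100, seed=5)
        assert r1.to_dict() == r2.to_dict()

    def test_p_floor_respected(self, tiny_matrix):
        low, high = tiny_matrix.sample_ids[:6], tiny_matrix.sample_ids[6:]
        r = ss.gsea_permutation_p(tiny_matrix, low, high, ["G0", "G1"], n_perm=100, seed=5)
        assert r.p_perm >= 1 / 101

    def test_null_sets_rarely_significant(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 20
        for rep in range(reps):
            m = matrix_from(rng.normal(0, 1, size=(60, 24)))
            low, high = m.sample_ids[:12], m.sample_ids[12:]
            members = list(rng.choice(m.probe_ids, size=8, replace=False))
            r = ss.gsea_permutation_p(m, low, high, members, n_perm=200, seed=rep)
            hits += r.p_perm <= 0.05
        assert hits <= 2  # >= 90% of repetitions non-significant

    def test_null_permutation_p_approximately_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for rep in range(200):
            m = matrix_from(rng.normal(0, 1, size=(30, 16)))
            members = list(rng.choice(m.probe_ids, size=5, replace=False))
            r = ss.gsea_permutation_p(
                m, m.sample_ids[:8], m.sample_ids[8:], members, n_perm=100, seed=1000 + rep
            )
            ps.append(r.p_perm)
        grid = np.linspace(0, 1, 101)
        ecdf = np.array([(np.asarray(ps) <= g).mean() for g in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.1


class TestCorrelateProbes:
    def test_self_correlation_is_one(self, tiny_matrix):
        r, _ = ss.correlate_probes(tiny_matrix, "G0", "G0")
        assert r == pytest.approx(1.0)

    def test_negation_is_minus_one(self, tiny_matrix):
        m = ss.ExpressionMatrix(
            pd.concat([tiny_matrix.values, (-tiny_matrix.values.loc["G0"]).to_frame("NEG").T])
        )
        r, p = ss.correlate_probes(m, "G0", "NEG")
        assert r == pytest.approx(-1.0) and p < 1e-10

    def test_independent_probes_weakly_correlated(self):
        rng = np.random.default_rng(2)
        m = matrix_from(rng.normal(size=(2, 500)))
        r, _ = ss.correlate_probes(m, "G0", "G1")
        assert abs(r) < 0.12  # ~2.5/sqrt(n) null bound

    def test_too_few_shared_samples_rejected(self):
        arr = np.array([[1.0, 2.0, np.nan, np.nan], [np.nan, np.nan, 1.0, 2.0]])
        with pytest.raises(ValueError):
            ss.correlate_probes(matrix_from(arr), "G0", "G1")
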