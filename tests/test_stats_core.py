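"""Oracle tests for the statistical kernel.

Every statistic is checked against an independent implementation: scipy /
statsmodels / scikit-learn reference routines, brute-force enumeration, or a
naive re-implementation from the defining formula.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from proxistress.stats_core import (
    ZeroVarianceError,
    bh_adjust,
    hypergeometric_tail,
    ora,
    pca_scores,
    preranked_gsea,
    two_sample_ttest,
)


# ---------------------------------------------------------------- t-test


class TestTwoSampleTTest:
    def test_identical_groups_give_t0_p1(self):
        res = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert res.t_stat == 0
        assert res.p == 1

    def test_pure_shift_gives_positive_t_and_exact_estimate(self):
        b = [4.1, 4.0, 4.2, 3.9]
        a = [x + 0.7 for x in b]
        res = two_sample_ttest(a, b)
        assert res.estimate == pytest.approx(0.7)
        assert res.t_stat > 0

    def test_hand_computed_pooled_variance_example(self):
        # textbook pooled-variance computation, done independently here
        a = np.array([5.1, 4.9, 5.3, 5.0])
        b = np.array([4.1, 4.0, 4.2, 3.9])
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t_expected = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        p_expected = 2 * sps.t.sf(abs(t_expected), 6)
        res = two_sample_ttest(a, b, equal_var=True)
        assert res.t_stat == pytest.approx(t_expected, abs=1e-12)
        assert res.p == pytest.approx(p_expected, abs=1e-12)
        assert res.df == 6

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_scipy_on_1000_random_instances(self, equal_var):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n_a = rng.integers(2, 10)
            n_b = rng.integers(2, 10)
            a = rng.normal(rng.normal(0, 2), rng.uniform(0.5, 3), n_a)
            b = rng.normal(0, rng.uniform(0.5, 3), n_b)
            res = two_sample_ttest(a, b, equal_var=equal_var)
            ref = sps.ttest_ind(a, b, equal_var=equal_var)
            assert res.t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_sign_of_t_matches_sign_of_estimate(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(rng.uniform(-2, 2), 1, 5)
            b = rng.normal(0, 1, 5)
            res = two_sample_ttest(a, b)
            assert np.sign(res.t_stat) == np.sign(res.estimate)

    def test_zero_variance_equal_groups_raise(self):
        with pytest.raises(ZeroVarianceError):
            two_sample_ttest([2.0, 2.0, 2.0], [2.0, 2.0])

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])


# ---------------------------------------------------------------- BH


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        # p=[0.01,0.02,0.03], m=3: q_(i) = min over j>=i of 3*p_(j)/j = 0.03
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_nan_propagates_and_does_not_count(self):
        p = [0.01, np.nan, 0.02, 0.03]
        q = bh_adjust(p)
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2, 3]], bh_adjust([0.01, 0.02, 0.03]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_q_at_least_p_and_monotone_in_p(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------- hypergeometric


def _brute_force_tail(k, K, n, N):
    """Exhaustive enumeration of P(X >= k) with exact integer combinatorics."""
    denom = math.comb(N, n)
    total = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    )
    return total / denom


class TestHypergeometricTail:
    def test_k0_is_one(self):
        assert hypergeometric_tail(0, 5, 5, 10) == 1.0

    def test_exact_combinatorial_case(self):
        # all 5 draws hit all 5 successes out of 10: 1/C(10,5)
        assert hypergeometric_tail(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_enumeration_case_n20(self):
        assert hypergeometric_tail(3, 6, 7, 20) == pytest.approx(
            _brute_force_tail(3, 6, 7, 20), rel=1e-12
        )

    def test_all_instances_up_to_N12_match_enumeration(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        ours = hypergeometric_tail(k, K, n, N)
                        ref = _brute_force_tail(k, K, n, N)
                        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12), (
                            k, K, n, N,
                        )

    def test_matches_scipy_sf_on_large_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            N = int(rng.integers(50, 5000))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            ours = hypergeometric_tail(k, K, n, N)
            ref = sps.hypergeom.sf(k - 1, N, K, n)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_tail(0, 11, 5, 10)


# ---------------------------------------------------------------- ORA


class TestORA:
    def test_perfect_overlap_attains_minimum_p(self):
        universe = [f"g{i}" for i in range(200)]
        sets = {"planted": universe[:10]}
        for j in range(5):
            sets[f"decoy{j}"] = universe[50 + 10 * j : 60 + 10 * j]
        table = ora(universe[:10], universe, sets)
        assert table.iloc[0]["set_name"] == "planted"
        assert table.iloc[0]["p_hyper"] == table["p_hyper"].min()

    def test_overlap_count_is_definitional(self):
        universe = [f"g{i}" for i in range(50)]
        selection = universe[:12]
        gene_set = universe[8:20] + ["not_in_universe"]
        table = ora(selection, universe, {"s": gene_set})
        assert table.iloc[0]["k"] == len(set(selection) & set(gene_set) & set(universe))
        assert table.iloc[0]["K"] == 12  # out-of-universe member dropped

    def test_zero_overlap_sets_are_skipped(self):
        universe = [f"g{i}" for i in range(20)]
        table = ora(universe[:5], universe, {"outside": ["x1", "x2", "x3"]})
        assert len(table) == 0
        assert table.attrs["skipped_sets"] == ["outside"]

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora(["a", "zzz"], ["a", "b"], {"s": ["a"]})

    def test_null_selection_calibration(self):
        # uniform random selections: ~5% of sets at p <= 0.05
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(400)]
        sets = {
            f"s{j}": list(rng.choice(universe, size=25, replace=False))
            for j in range(20)
        }
        hits = 0
        total = 0
        for _ in range(500):
            selection = rng.choice(universe, size=40, replace=False)
            table = ora(selection, universe, sets)
            hits += int((table["p_hyper"] <= 0.05).sum())
            total += len(table)
        frac = hits / total
        # discreteness makes the tail conservative; allow 3 binomial SE
        se = math.sqrt(0.05 * 0.95 / total)
        assert frac <= 0.05 + 3 * se


# ---------------------------------------------------------------- GSEA


def _naive_es(ranked_ids, metric, members, p_weight):
    """O(N*|S|) running-sum oracle, straight from the definition."""
    members = set(members)
    order = np.argsort(-np.asarray(metric), kind="stable")
    ids_sorted = [ranked_ids[i] for i in order]
    m_sorted = [metric[i] for i in order]
    nh = sum(1 for g in ids_sorted if g in members)
    total_w = sum(abs(m_sorted[i]) ** p_weight for i, g in enumerate(ids_sorted) if g in members)
    running = 0.0
    path = []
    for i, g in enumerate(ids_sorted):
        if g in members:
            if total_w > 0:
                running += abs(m_sorted[i]) ** p_weight / total_w
            else:
                running += 1.0 / nh
        else:
            running -= 1.0 / (len(ids_sorted) - nh)
        path.append(running)
    hi, lo = max(path), min(path)
    # signed maximum deviation; positive wins an exact magnitude tie
    return hi if hi >= -lo else lo


class TestPrerankedGSEA:
    def _ranked(self, n, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(n)]
        metric = rng.normal(size=n)
        return ids, metric

    def test_top2_of_10_unweighted_es_is_one(self):
        ids = [f"g{i}" for i in range(10)]
        metric = list(np.linspace(5, 0.5, 10))
        table = preranked_gsea(
            list(zip(ids, metric)), {"top": ids[:2]}, p_weight=0, n_perm=10,
            seed=1, min_size=2,
        )
        assert table.iloc[0]["es"] == pytest.approx(1.0)

    def test_es_matches_naive_oracle_unweighted_small_lists(self):
        rng = np.random.default_rng(9)
        for case in range(30):
            n = int(rng.integers(10, 51))
            ids, metric = self._ranked(n, seed=case)
            size = int(rng.integers(3, max(4, n // 3)))
            members = list(rng.choice(ids, size=size, replace=False))
            table = preranked_gsea(
                list(zip(ids, metric)), {"s": members}, p_weight=0,
                n_perm=10, seed=0, min_size=2,
            )
            expected = _naive_es(ids, metric, members, 0)
            assert table.iloc[0]["es"] == pytest.approx(expected, abs=1e-12)

    def test_es_matches_naive_oracle_weighted(self):
        ids, metric = self._ranked(40, seed=4)
        members = [ids[i] for i in (0, 3, 7, 20, 33)]
        table = preranked_gsea(
            list(zip(ids, metric)), {"s": members}, p_weight=1,
            n_perm=10, seed=0, min_size=2,
        )
        assert table.iloc[0]["es"] == pytest.approx(
            _naive_es(ids, metric, members, 1), abs=1e-12
        )

    def test_negating_metric_negates_es(self):
        ids, metric = self._ranked(30, seed=2)
        members = ids[5:12]
        t1 = preranked_gsea(
            list(zip(ids, metric)), {"s": members}, n_perm=20, seed=3, min_size=2
        )
        t2 = preranked_gsea(
            list(zip(ids, [-m for m in metric])), {"s": members},
            n_perm=20, seed=3, min_size=2,
        )
        assert t2.iloc[0]["es"] == pytest.approx(-t1.iloc[0]["es"], abs=1e-12)

    def test_seeded_determinism(self):
        ids, metric = self._ranked(100, seed=6)
        sets = {"a": ids[:15], "b": ids[40:60]}
        t1 = preranked_gsea(list(zip(ids, metric)), sets, n_perm=50, seed=42)
        t2 = preranked_gsea(list(zip(ids, metric)), sets, n_perm=50, seed=42)
        pd.testing.assert_frame_equal(t1, t2)

    def test_uniformly_spread_set_is_null_like(self):
        # members evenly through the list: |NES| near 1, p rarely small
        n_small_p = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            ids = [f"g{i}" for i in range(500)]
            metric = list(rng.normal(size=500))
            members = ids[::25]  # 20 evenly spaced by input id, random in rank
            table = preranked_gsea(
                list(zip(ids, metric)), {"s": members}, n_perm=100, seed=seed
            )
            if table.iloc[0]["p_perm"] <= 0.05:
                n_small_p += 1
        assert n_small_p <= 0.10 * reps + 2

    def test_rejects_nonfinite_metric_and_tiny_nperm(self):
        ids = [f"g{i}" for i in range(20)]
        with pytest.raises(ValueError):
            preranked_gsea(list(zip(ids, [np.inf] * 20)), {"s": ids[:6]})
        with pytest.raises(ValueError):
            preranked_gsea(
                list(zip(ids, np.arange(20.0))), {"s": ids[:6]}, n_perm=5
            )

    def test_leading_edge_is_subset_of_members_in_list(self):
        ids, metric = self._ranked(60, seed=8)
        members = ids[:10] + ["absent_gene"]
        table = preranked_gsea(
            list(zip(ids, metric)), {"s": members}, n_perm=20, seed=0
        )
        le = table.iloc[0]["leading_edge"]
        assert set(le) <= (set(members) & set(ids))


# ---------------------------------------------------------------- PCA


class TestPCAScores:
    def test_rank_one_data_explains_everything(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=30)
        weights = rng.normal(size=8)
        data = pd.DataFrame(np.outer(direction, weights))
        scores, evr = pca_scores(data, n_components=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_shift_leaves_scores_unchanged(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(40, 6)))
        s1, _ = pca_scores(data, 2)
        s2, _ = pca_scores(data + 7.5, 2)
        pd.testing.assert_frame_equal(s1, s2, atol=1e-9, rtol=0)

    def test_matches_sklearn_up_to_sign(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(50, 8)))
        scores, evr = pca_scores(data, 3)
        ref = PCA(n_components=3).fit(data.to_numpy().T)
        ref_scores = ref.transform(data.to_numpy().T)
        for j in range(3):
            ours = scores.iloc[:, j].to_numpy()
            theirs = ref_scores[:, j]
            agree = np.allclose(ours, theirs, atol=1e-8)
            flipped = np.allclose(ours, -theirs, atol=1e-8)
            assert agree or flipped
        np.testing.assert_allclose(evr, ref.explained_variance_ratio_, atol=1e-9)

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(4)
        base = rng.normal(25, 2, size=(100, 1))
        cluster_a = base + rng.normal(0, 0.1, size=(100, 4))
        cluster_b = base + 1.0 + rng.normal(0, 0.1, size=(100, 4))
        data = pd.DataFrame(np.hstack([cluster_a, cluster_b]))
        scores, _ = pca_scores(data, 1)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:4] < pc1[4:].min()).all() or (pc1[:4] > pc1[4:].max()).all()

    def test_missing_values_rejected(self):
        data = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            pca_scores(data, 1)
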