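"""Closed-form KL/sKL divergences, pairwise matrices, agglomeration, cuts,
and cluster summaries."""

import numpy as np
import pytest

from phenotrace.cluster import (
    DivergenceMatrix,
    agglomerate,
    cut,
    kl_diag_gauss,
    pairwise,
    skl,
    summarize,
)
from phenotrace.preprocess import TraceMatrix
from phenotrace.vae import LatentGaussian, LatentTable


def _lg(mu, var):
    return LatentGaussian(np.atleast_1d(np.asarray(mu, float)),
                          np.atleast_1d(np.asarray(var, float)))


class TestDivergenceProperties:
    """Algebraic invariants of the divergences over random Gaussians."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    gaussians = st.tuples(
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.lists(st.floats(0.1, 5), min_size=3, max_size=3),
    )

    @given(gaussians, gaussians)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_kl_nonnegative_and_skl_symmetric(self, a, b):
        p, q = _lg(*a), _lg(*b)
        assert kl_diag_gauss(p, q) >= -1e-12
        assert skl(p, q) == pytest.approx(skl(q, p), rel=1e-10, abs=1e-12)

    @given(gaussians)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_self_divergence_zero(self, a):
        p = _lg(*a)
        assert kl_diag_gauss(p, p) == 0.0
        assert skl(p, p) == 0.0


class TestKL:
    def test_zero_iff_equal(self):
        p = _lg([1.0, -2.0], [0.5, 3.0])
        assert kl_diag_gauss(p, p) == 0.0
        q = _lg([1.0, -2.1], [0.5, 3.0])
        assert kl_diag_gauss(p, q) > 0.0

    def test_unit_shift_1d(self):
        assert kl_diag_gauss(_lg(0.0, 1.0), _lg(1.0, 1.0)) == pytest.approx(0.5)

    def test_matches_monte_carlo_3d(self):
        rng = np.random.default_rng(0)
        p = _lg(rng.normal(size=3), rng.uniform(0.5, 2, size=3))
        q = _lg(rng.normal(size=3), rng.uniform(0.5, 2, size=3))
        n = 1_000_000
        z = p.mu + np.sqrt(p.var) * rng.standard_normal((n, 3))
        log_p = -0.5 * np.sum((z - p.mu) ** 2 / p.var + np.log(2 * np.pi * p.var), axis=1)
        log_q = -0.5 * np.sum((z - q.mu) ** 2 / q.var + np.log(2 * np.pi * q.var), axis=1)
        diff = log_p - log_q
        mc, se = diff.mean(), diff.std() / np.sqrt(n)
        assert abs(kl_diag_gauss(p, q) - mc) < 3 * se

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_diag_gauss(_lg([0.0], [1.0]), _lg([0.0, 0.0], [1.0, 1.0]))


class TestSKL:
    def test_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = _lg(rng.normal(size=4), rng.uniform(0.2, 3, size=4))
            q = _lg(rng.normal(size=4), rng.uniform(0.2, 3, size=4))
            assert skl(p, q) == pytest.approx(skl(q, p), rel=1e-12)

    def test_zero_at_equality(self):
        p = _lg([0.3], [2.0])
        assert skl(p, p) == 0.0

    def test_variance_ratio_case_exact(self):
        # N(0,1) vs N(0,4): KL terms 0.5(ln4 − 0.75) and 0.5(3 − ln4); logs cancel
        assert skl(_lg(0.0, 1.0), _lg(0.0, 4.0)) == pytest.approx(0.5625, abs=1e-12)


class TestPairwise:
    def _table(self, mu, var):
        mu = np.asarray(mu, float)
        return LatentTable(np.arange(len(mu)), mu, np.asarray(var, float))

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        t = self._table(rng.normal(size=(3, 4)), rng.uniform(0.5, 2, size=(3, 4)))
        D = pairwise(t)
        np.testing.assert_allclose(D.values, D.values.T)
        np.testing.assert_array_equal(np.diag(D.values), 0.0)
        assert len(set(D.values[np.triu_indices(3, 1)])) == 3

    def test_duplicate_cells_zero_entry(self):
        mu = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        var = np.ones((3, 2))
        D = pairwise(self._table(mu, var))
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_per_pair_calls(self):
        rng = np.random.default_rng(3)
        mu = rng.normal(size=(5, 6))
        var = rng.uniform(0.3, 2.5, size=(5, 6))
        t = self._table(mu, var)
        D = pairwise(t)
        for i in range(5):
            for j in range(5):
                expected = skl(t.row(i), t.row(j)) if i != j else 0.0
                assert D.values[i, j] == pytest.approx(expected, abs=1e-9)


class TestAgglomerate:
    def _two_groups(self):
        # two tight groups: within-group sKL tiny, between-group huge
        mu = np.array([[0.0], [0.05], [0.1], [10.0], [10.05], [10.1]])
        var = np.ones((6, 1))
        return LatentTable(np.arange(6), mu, var)

    def test_merge_count(self):
        D = pairwise(self._two_groups())
        tree = agglomerate(D)
        assert len(tree.linkage_matrix) == 5

    def test_two_groups_recovered_at_top_split(self):
        D = pairwise(self._two_groups())
        tree = agglomerate(D)
        heights = tree.merge_heights
        thr = 0.5 * (heights[-1] + heights[-2])
        a = cut(tree, threshold=thr)
        assert a.n_clusters == 2
        labels = a.labels
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_average_linkage_heights_monotone(self):
        rng = np.random.default_rng(4)
        t = LatentTable(
            np.arange(20), rng.normal(size=(20, 3)), rng.uniform(0.5, 2, size=(20, 3))
        )
        tree = agglomerate(pairwise(t))
        assert np.all(np.diff(tree.merge_heights) >= -1e-12)

    def test_too_few_items_rejected(self):
        D = DivergenceMatrix(np.zeros((1, 1)), np.array([0]))
        with pytest.raises(ValueError):
            agglomerate(D)


class TestCut:
    @pytest.fixture(scope="class")
    @staticmethod
    def tree():
        rng = np.random.default_rng(5)
        t = LatentTable(
            np.arange(12), rng.normal(size=(12, 2)), rng.uniform(0.5, 2, size=(12, 2))
        )
        return agglomerate(pairwise(t))

    def test_k_equals_n_singletons(self, tree):
        a = cut(tree, k=12)
        assert a.n_clusters == 12

    def test_k_one_single_cluster(self, tree):
        a = cut(tree, k=1)
        assert a.n_clusters == 1
        assert a.counts[1] == 12

    def test_counts_sum_to_n(self, tree):
        a = cut(tree, k=4)
        assert sum(a.counts.values()) == 12
        assert set(np.unique(a.labels)) == set(range(1, a.n_clusters + 1))

    def test_exactly_one_criterion_required(self, tree):
        with pytest.raises(ValueError):
            cut(tree)
        with pytest.raises(ValueError):
            cut(tree, threshold=1.0, k=2)
        with pytest.raises(ValueError):
            cut(tree, k=13)

    def test_threshold_refinement_only_splits(self, tree):
        """Hierarchical nesting: lowering the threshold never merges."""
        hmax = tree.merge_heights[-1]
        thresholds = np.linspace(hmax * 1.01, 1e-6, 10)
        prev = cut(tree, threshold=thresholds[0]).labels
        for thr in thresholds[1:]:
            cur = cut(tree, threshold=thr).labels
            # each current cluster maps into exactly one previous cluster
            for c in np.unique(cur):
                assert len(np.unique(prev[cur == c])) == 1
            prev = cur


class TestSummarize:
    def test_counts_and_identical_cluster_mean(self):
        data = np.zeros((4, 3, 750))
        data[:2] = 0.5  # cluster of identical traces
        data[2:, 2] = np.linspace(0, 1, 750)
        m = TraceMatrix(
            data=data, time=np.linspace(0, 3, 750), cell_ids=np.arange(4)
        )
        from phenotrace.cluster import ClusterAssignment

        a = ClusterAssignment(labels=np.array([1, 1, 2, 2]), cell_ids=np.arange(4))
        s = summarize(a, m)
        assert s.counts == {1: 2, 2: 2}
        np.testing.assert_allclose(s.mean_traces[1], 0.5)

    def test_cluster_means_match_generator_kinetics(self, small_dataset, small_matrix):
        """Clusters formed from ground-truth labels reproduce the generator's
        noiseless kinetics within a few noise SDs."""
        from phenotrace.cluster import ClusterAssignment
        from phenotrace.preprocess import resample
        from phenotrace.synthetic import make_phenotype_library

        names = sorted(set(small_dataset.labels))
        label_idx = np.array([names.index(l) for l in small_dataset.labels]) + 1
        a = ClusterAssignment(labels=label_idx, cell_ids=small_matrix.cell_ids)
        s = summarize(a, small_matrix)
        t = small_dataset.time_grid()
        noise_sd = small_dataset.config.noise_sd
        for ci, name in enumerate(names, start=1):
            spec = make_phenotype_library([name])[0]
            _, expected = resample(t, spec.mean_trace(t), 750)
            rms = np.sqrt(np.mean((s.mean_traces[ci] - expected) ** 2))
            assert rms < 3 * noise_sd

    def test_misaligned_rejected(self, small_matrix):
        from phenotrace.cluster import ClusterAssignment

        a = ClusterAssignment(labels=np.ones(3, dtype=int), cell_ids=np.arange(3))
        with pytest.raises(ValueError):
            summarize(a, small_matrix)
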