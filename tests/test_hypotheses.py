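"""Sharpness scoring, fate labeling, KS testing, and the spatial analyses."""

from itertools import combinations

import numpy as np
import pytest

from phenotrace.cluster import ClusterAssignment, summarize
from phenotrace.hypotheses import (
    impact_signature_report,
    ks_two_sample,
    label_fate,
    late_death_regression,
    mito_distance_test,
    sharpness_scores,
)
from phenotrace.preprocess import TraceMatrix
from phenotrace.synthetic import simulate_impact_calcium


class TestSharpnessScores:
    def test_identical_traces_degenerate(self):
        X = np.tile(simulate_impact_calcium(0.5), (5, 1))
        res = sharpness_scores(X)
        assert res.degenerate
        np.testing.assert_array_equal(res.scores, 0.0)

    def test_sharp_vs_plateau_fully_separated(self):
        X = np.vstack(
            [np.tile(simulate_impact_calcium(0.9), (50, 1)) + 0,
             np.tile(simulate_impact_calcium(0.1), (50, 1))]
        )
        # tiny jitter so PCA is non-degenerate within groups
        rng = np.random.default_rng(0)
        X = X + rng.normal(0, 1e-6, size=X.shape)
        res = sharpness_scores(X)
        sharp, plateau = res.scores[:50], res.scores[50:]
        assert sharp.min() > plateau.max()  # AUC = 1
        assert res.pc1_evr > 0.5

    def test_sign_oriented_to_early_intensity(self):
        rng = np.random.default_rng(1)
        sharp_vals = rng.uniform(0, 1, size=40)
        X = np.stack([simulate_impact_calcium(s) for s in sharp_vals])
        res = sharpness_scores(X)
        assert np.corrcoef(res.scores, sharp_vals)[0, 1] > 0.9

    def test_zero_max_traces_dropped(self):
        X = np.vstack([simulate_impact_calcium(0.3), np.zeros(2400),
                       simulate_impact_calcium(0.8)])
        res = sharpness_scores(X)
        np.testing.assert_array_equal(res.dropped, [1])
        assert len(res.scores) == 2


class TestLabelFate:
    def _matrix(self, nmp_levels):
        n = len(nmp_levels)
        data = np.zeros((n, 3, 750))
        for i, lv in enumerate(nmp_levels):
            data[i, 2] = lv
        return TraceMatrix(
            data=data, time=np.linspace(0, 3, 750), cell_ids=np.arange(n)
        )

    def test_high_nmp_clusters_labeled_dead(self):
        m = self._matrix([0.05, 0.06, 0.9, 0.85])
        a = ClusterAssignment(labels=np.array([1, 1, 2, 2]), cell_ids=np.arange(4))
        fate, flagged = label_fate(summarize(a, m), a)
        np.testing.assert_array_equal(fate, ["viable", "viable", "dead", "dead"])
        assert not flagged

    def test_single_cluster_flagged(self):
        m = self._matrix([0.1, 0.1])
        a = ClusterAssignment(labels=np.array([1, 1]), cell_ids=np.arange(2))
        fate, flagged = label_fate(summarize(a, m), a)
        assert flagged
        assert len(set(fate)) == 1

    def test_labels_partition_cells(self):
        m = self._matrix([0.1, 0.5, 0.9, 0.2, 0.8])
        a = ClusterAssignment(
            labels=np.array([1, 2, 3, 1, 3]), cell_ids=np.arange(5)
        )
        fate, _ = label_fate(summarize(a, m), a)
        assert ((fate == "dead") | (fate == "viable")).all()
        assert len(fate) == 5


class TestKSTwoSample:
    def test_identical_samples(self):
        a = np.arange(10.0)
        D, p = ks_two_sample(a, a)
        assert D == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        D, p = ks_two_sample(np.arange(100.0), np.arange(200.0, 300.0))
        assert D == 1.0
        assert p < 1e-10

    def test_exact_p_matches_permutation_enumeration(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=5)
        b = rng.normal(size=5) + 0.5
        D, p = ks_two_sample(a, b)
        pool = np.concatenate([a, b])

        def ks_stat(x, y):
            grid = np.sort(pool)
            cx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
            cy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
            return np.abs(cx - cy).max()

        count = total = 0
        for idx in combinations(range(10), 5):
            x = pool[list(idx)]
            y = pool[[i for i in range(10) if i not in idx]]
            total += 1
            count += ks_stat(x, y) >= D - 1e-12
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample(np.array([]), np.arange(3.0))


class TestLateDeathRegression:
    def _matrix_with_death_times(self, positions, death_times_h):
        n = len(positions)
        t = np.linspace(0, 3, 750)
        data = np.zeros((n, 3, 750))
        for i, td in enumerate(death_times_h):
            data[i, 2] = np.exp(-((t - td) ** 2) / (2 * 0.05**2))
        return TraceMatrix(
            data=data, time=t, cell_ids=np.arange(n),
            positions=np.asarray(positions, float),
        )

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(100, 500, 50), np.full(50, 80.0)])
        dist = np.abs(pos[:, 0] - 330.0)
        death = 1.1 + 0.004 * dist  # hours, all late
        m = self._matrix_with_death_times(pos, death)
        rep = late_death_regression(m, (330.0, 80.0))
        assert rep.extras["slope_h_per_um"] == pytest.approx(0.004, rel=0.02)
        assert rep.p_value < 1e-10

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 660, size=(40, 2))
        death = rng.uniform(1.2, 2.8, size=40)
        m = self._matrix_with_death_times(pos, death)
        rep = late_death_regression(m, (330.0, 80.0))
        from scipy import stats

        dist = np.hypot(pos[:, 0] - 330.0, pos[:, 1] - 80.0)
        td = m.time[np.argmax(m.data[:, 2, :], axis=1)]
        sel = td > 1.0
        lr = stats.linregress(dist[sel], td[sel])
        assert rep.statistic == pytest.approx((lr.slope / lr.stderr) ** 2, rel=1e-9)

    def test_early_deaths_excluded(self):
        pos = np.random.default_rng(2).uniform(0, 660, size=(30, 2))
        death = np.full(30, 0.5)  # all early
        m = self._matrix_with_death_times(pos, death)
        rep = late_death_regression(m, (330.0, 80.0))
        assert rep.config.get("insufficient_data")
        assert np.isnan(rep.p_value)

    def test_null_rejection_rate_calibrated(self):
        """Type-I error at alpha=0.05 within [0.02, 0.09] over 200 null sims."""
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            pos = rng.uniform(0, 660, size=(60, 2))
            death = rng.uniform(1.2, 2.9, size=60)  # independent of distance
            m = self._matrix_with_death_times(pos, death)
            rep = late_death_regression(m, (330.0, 80.0))
            rejections += rep.p_value < 0.05
        assert 0.02 <= rejections / n_reps <= 0.09


class TestMitoDistance:
    def test_biased_low_group_detected(self):
        rng = np.random.default_rng(0)
        impact = (330.0, 330.0)
        high = rng.uniform(0, 660, size=(500, 2))
        # low-TMRM cells biased toward impact with exp(−d/100) acceptance
        low = []
        while len(low) < 500:
            cand = rng.uniform(0, 660, size=2)
            d = np.hypot(cand[0] - impact[0], cand[1] - impact[1])
            if rng.uniform() < np.exp(-d / 100.0):
                low.append(cand)
        pos = np.vstack([high, low])
        labels = np.array(["high"] * 500 + ["low"] * 500)
        rep = mito_distance_test(labels, pos, impact)
        assert rep.p_value < 0.01
        assert rep.extras["low_median_um"] < rep.extras["high_median_um"]

    def test_medians_reported_exactly(self):
        pos = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0], [9.0, 12.0]])
        labels = np.array(["high", "high", "low", "low"])
        rep = mito_distance_test(labels, pos, (0.0, 0.0))
        assert rep.extras["high_median_um"] == pytest.approx(2.5)
        assert rep.extras["low_median_um"] == pytest.approx(12.5)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            mito_distance_test(
                np.array(["high", "high"]), np.zeros((2, 2)), (0.0, 0.0)
            )


class TestImpactSignatureReport:
    def _setup(self):
        rng = np.random.default_rng(3)
        n = 20
        sharp = np.concatenate([rng.uniform(0.7, 1.0, 10), rng.uniform(0.0, 0.3, 10)])
        impact_ca = np.stack([simulate_impact_calcium(s) for s in sharp])
        data = rng.uniform(0, 1, size=(n, 3, 750))
        m = TraceMatrix(
            data=data, time=np.linspace(0, 3, 750), cell_ids=np.arange(n),
            positions=rng.uniform(0, 660, size=(n, 2)),
        )
        a = ClusterAssignment(
            labels=np.array([1] * 10 + [2] * 10), cell_ids=np.arange(n)
        )
        return a, impact_ca, m

    def test_entry_count_and_member_means(self):
        a, impact_ca, m = self._setup()
        report = impact_signature_report(a, impact_ca, m)
        assert set(report) == {1, 2}
        np.testing.assert_allclose(
            report[1]["mean_impact_calcium"], impact_ca[:10].mean(axis=0)
        )
        np.testing.assert_allclose(
            report[2]["mean_long_term"], m.data[10:].mean(axis=0)
        )

    def test_sharp_cluster_peaks_earlier(self):
        a, impact_ca, m = self._setup()
        report = impact_signature_report(a, impact_ca, m)
        peak1 = np.argmax(report[1]["mean_impact_calcium"])
        peak2 = np.argmax(report[2]["mean_impact_calcium"])
        assert peak1 < peak2

    def test_empty_rejected(self):
        a, impact_ca, m = self._setup()
        empty = ClusterAssignment(labels=np.array([]), cell_ids=np.array([]))
        with pytest.raises(ValueError):
            impact_signature_report(empty, impact_ca, m)
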