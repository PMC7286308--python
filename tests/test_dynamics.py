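import numpy as np
import pytest

from bna.dynamics import (
    FCStateClusterer,
    StateModel,
    _corr_trace,
    _l1_distances,
    cluster_states,
    detect_qpp,
    dwell_and_transitions,
    phase_align,
    phase_randomized_surrogate,
    sliding_fc,
)
from bna.preprocess import ROITimeSeries
from bna.synthdata import make_qpp_pattern


class TestCorrTrace:
    def test_periodic_tiling_peaks_at_one(self):
        W, M = 10, 4
        pat = make_qpp_pattern(W, M, seed=0)
        data = np.tile(pat, (8, 1))
        trace = _corr_trace(pat, data)
        starts = np.arange(0, data.shape[0] - W + 1, W)
        np.testing.assert_allclose(trace[starts], 1.0, atol=1e-9)

    def test_matches_per_roi_pearson_oracle(self, rng):
        W, M = 6, 3
        pat = rng.standard_normal((W, M))
        data = rng.standard_normal((30, M))
        trace = _corr_trace(pat, data)
        for lag in [0, 7, 24]:
            win = data[lag : lag + W]
            cors = [np.corrcoef(win[:, j], pat[:, j])[0, 1] for j in range(M)]
            assert trace[lag] == pytest.approx(np.mean(cors), abs=1e-10)


class TestDetect:
    def test_constant_signal_rejected(self):
        data = np.ones((300, 4))
        with pytest.raises(ValueError):
            detect_qpp(ROITimeSeries(data=data), window_s=20)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            detect_qpp(ROITimeSeries(data=rng.standard_normal((40, 4))), window_s=20)

    def test_determinism(self, rng):
        data = rng.standard_normal((400, 5))
        a = detect_qpp(ROITimeSeries(data=data), n_random_starts=3, seed=7)
        b = detect_qpp(ROITimeSeries(data=data), n_random_starts=3, seed=7)
        np.testing.assert_array_equal(a.pattern, b.pattern)


class TestSurrogates:
    def test_preserves_amplitude_spectrum(self, rng):
        x = rng.standard_normal((256, 3))
        surr = phase_randomized_surrogate(x, rng)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(x, axis=0)), np.abs(np.fft.rfft(surr, axis=0)),
            atol=1e-8,
        )

    def test_preserves_cross_correlation(self, rng):
        base = rng.standard_normal(1024)
        x = np.column_stack([base, 0.8 * base + 0.6 * rng.standard_normal(1024)])
        surr = phase_randomized_surrogate(x, rng)
        r_orig = np.corrcoef(x.T)[0, 1]
        r_surr = np.corrcoef(surr.T)[0, 1]
        assert abs(r_orig - r_surr) < 0.1


class TestPhaseAlign:
    def test_exact_roll_recovered(self, rng):
        a = rng.standard_normal((12, 5))
        b = np.roll(a, 5, axis=0)
        shift, corr = phase_align(a, b)
        assert shift == 5
        assert corr == pytest.approx(1.0)

    def test_sign_flip_mirrors_self_alignment(self, rng):
        """Aligning a against -a maximizes -corr(roll(a, s), a): the best
        achievable is minus the most negative circular self-correlation."""
        a = rng.standard_normal((12, 4))
        self_corrs = [
            np.corrcoef(np.roll(a, s, axis=0).ravel(), a.ravel())[0, 1]
            for s in range(12)
        ]
        _, corr = phase_align(a, -a)
        assert corr == pytest.approx(-min(self_corrs), abs=1e-12)

    def test_matches_exhaustive_oracle(self, rng):
        a = rng.standard_normal((9, 3))
        b = rng.standard_normal((9, 3))
        shift, corr = phase_align(a, b)
        brute = [
            np.corrcoef(np.roll(a, s, axis=0).ravel(), b.ravel())[0, 1]
            for s in range(9)
        ]
        assert corr == pytest.approx(max(brute), abs=1e-12)
        assert shift == int(np.argmax(brute))


class TestSlidingFC:
    def test_single_window_equals_full_fc(self, rng):
        data = rng.standard_normal((50, 4))
        ts = ROITimeSeries(data=data, tr_s=0.72)
        stack = sliding_fc(ts, window_s=36.0, step_frames=1)
        assert stack.n_windows == 1
        r = np.corrcoef(data.T)
        np.testing.assert_allclose(
            stack.matrices[0], np.arctanh(np.clip(r, -1 + 1e-6, 1 - 1e-6)),
            atol=1e-12,
        )

    def test_fisher_transform_value(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493061443)

    def test_stationary_null_fluctuations_small(self, rng):
        data = rng.standard_normal((600, 6))
        ts = ROITimeSeries(data=data, tr_s=0.72)
        stack = sliding_fc(ts, window_s=36.0, step_frames=10)
        off = stack.vectorized()
        assert np.mean(np.abs(off)) < 0.2

    def test_window_count_and_starts(self, rng):
        ts = ROITimeSeries(data=rng.standard_normal((120, 3)), tr_s=1.0)
        stack = sliding_fc(ts, window_s=36.0, step_frames=5)
        assert stack.n_windows == (120 - 36) // 5 + 1
        assert stack.starts[0] == 0 and stack.starts[-1] <= 120 - 36

    def test_window_longer_than_scan_rejected(self, rng):
        ts = ROITimeSeries(data=rng.standard_normal((20, 3)), tr_s=1.0)
        with pytest.raises(ValueError, match="longer"):
            sliding_fc(ts, window_s=36.0)


class TestClusterStates:
    def test_identical_windows_collapse(self):
        X = np.tile(np.arange(6.0), (10, 1))
        model = cluster_states(X, k=2, n_restarts=3, seed=0)
        assert np.unique(model.labels).size <= 2
        assert model.cost == pytest.approx(0.0)

    def test_k_equals_n_perfect_fit(self, rng):
        X = rng.standard_normal((5, 8))
        model = cluster_states(X, k=5, n_restarts=5, seed=1)
        assert model.cost == pytest.approx(0.0)
        assert np.unique(model.labels).size == 5

    def test_rejects_too_few_windows(self, rng):
        with pytest.raises(ValueError):
            cluster_states(rng.standard_normal((3, 4)), k=7)

    def test_centers_are_medians_of_members(self, rng):
        X = np.vstack([rng.normal(-5, 0.1, (20, 4)), rng.normal(5, 0.1, (20, 4))])
        model = cluster_states(X, k=2, n_restarts=3, seed=2)
        for j in range(2):
            members = X[model.labels == j + 1]
            np.testing.assert_allclose(
                model.centers[j], np.median(members, axis=0), atol=1e-12
            )

    def test_cost_is_total_l1_to_assigned_center(self, rng):
        X = rng.standard_normal((30, 5))
        model = cluster_states(X, k=3, n_restarts=4, seed=3)
        d = _l1_distances(X, model.centers)
        assert model.cost == pytest.approx(
            d[np.arange(30), model.labels - 1].sum()
        )

    def test_estimator_wrapper_predict(self, rng):
        X = np.vstack([rng.normal(-3, 0.2, (15, 4)), rng.normal(3, 0.2, (15, 4))])
        est = FCStateClusterer(n_clusters=2, n_restarts=3, random_state=0).fit(X)
        assert est.labels_.shape == (30,)
        np.testing.assert_array_equal(est.predict(X), est.labels_)


class TestDwellTransitions:
    def test_hand_counted_example(self):
        model = StateModel(
            centers=np.zeros((2, 3)), labels=np.array([1, 1, 1, 2, 2]), cost=0.0
        )
        model = dwell_and_transitions(model, step_s=1.0)
        assert model.dwell_times_s == {1: [3.0], 2: [2.0]}
        np.testing.assert_array_equal(model.transition_matrix, [[0, 1], [0, 0]])
        assert model.n_states_observed == 2

    def test_single_state_has_zero_transitions(self):
        model = StateModel(
            centers=np.zeros((3, 2)), labels=np.ones(6, dtype=int), cost=0.0
        )
        model = dwell_and_transitions(model, step_s=0.72)
        assert model.n_states_observed == 1
        assert np.all(model.transition_matrix == 0)
        assert model.dwell_times_s == {1: [6 * 0.72]}

    def test_alternating_labels(self):
        model = StateModel(
            centers=np.zeros((2, 2)), labels=np.array([1, 2, 1, 2]), cost=0.0
        )
        model = dwell_and_transitions(model, step_s=1.0)
        assert model.transition_matrix[0, 1] == pytest.approx(1.0)
        assert model.transition_matrix[1, 0] == pytest.approx(1.0)

    def test_rows_sum_to_one_or_zero_and_dwells_cover_scan(self, rng):
        labels = rng.integers(1, 5, size=60)
        model = StateModel(centers=np.zeros((4, 2)), labels=labels, cost=0.0)
        model = dwell_and_transitions(model, step_s=2.0)
        sums = model.transition_matrix.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))
        total = sum(sum(v) for v in model.dwell_times_s.values())
        assert total == pytest.approx(60 * 2.0)
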