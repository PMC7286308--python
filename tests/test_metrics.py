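import numpy as np
import pytest

from bna.metrics import (
    FCMatrix,
    fc,
    fc_similarity,
    mse_per_roi,
    persistence_forecast,
    power_slope,
    r2_per_step,
    r2_score_pooled,
)
from bna.preprocess import ROITimeSeries


def brute_force_r2(pred, act):
    """Per-region 1 - SSE/SST with explicit loops."""
    vals = []
    for j in range(act.shape[1]):
        mean = sum(act[:, j]) / len(act)
        sst = sum((a - mean) ** 2 for a in act[:, j])
        sse = sum((a - p) ** 2 for a, p in zip(act[:, j], pred[:, j]))
        vals.append(1 - sse / sst)
    return sum(vals) / len(vals)


class TestR2:
    def test_perfect_fit(self, rng):
        x = rng.standard_normal((3, 4, 6))
        np.testing.assert_allclose(r2_per_step(x, x), np.ones(3))

    def test_mean_prediction_scores_zero(self, rng):
        act = rng.standard_normal((50, 3))
        pred = np.tile(act.mean(axis=0), (50, 1))
        assert r2_score_pooled(pred, act) == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_example(self):
        act = np.array([[0.0], [1.0], [2.0]])
        pred = np.array([[0.0], [1.0], [1.0]])
        assert r2_score_pooled(pred, act) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self, rng):
        pred = rng.standard_normal((40, 5))
        act = rng.standard_normal((40, 5))
        assert abs(r2_score_pooled(pred, act) - brute_force_r2(pred, act)) < 1e-10

    def test_rejects_zero_variance(self):
        act = np.ones((10, 2))
        with pytest.raises(ValueError, match="variance"):
            r2_score_pooled(act, act)


class TestMSE:
    def test_identical_is_zero_and_constant_residual(self, rng):
        x = rng.standard_normal((20, 4))
        np.testing.assert_array_equal(mse_per_roi(x, x), np.zeros(4))
        np.testing.assert_allclose(mse_per_roi(x + 0.3, x), np.full(4, 0.09))

    def test_matches_naive_loop_oracle(self, rng):
        pred = rng.standard_normal((30, 4))
        act = rng.standard_normal((30, 4))
        naive = [
            sum((pred[t, j] - act[t, j]) ** 2 for t in range(30)) / 30
            for j in range(4)
        ]
        np.testing.assert_allclose(mse_per_roi(pred, act), naive, atol=1e-10)


class TestFC:
    def test_duplicate_and_negated_regions(self, rng):
        base = rng.standard_normal(100)
        data = np.column_stack([base, base, -base])
        m = fc(ROITimeSeries(data=data)).values
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)

    def test_matches_covariance_normalization_oracle(self, rng):
        x = rng.standard_normal((200, 5))
        m = fc(ROITimeSeries(data=x)).values
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (200 - 1)
        d = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(m, cov / np.outer(d, d), atol=1e-10)

    def test_valid_correlation_matrix(self, rng):
        m = fc(ROITimeSeries(data=rng.standard_normal((50, 6)))).values
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), np.ones(6), atol=1e-12)
        assert np.min(np.linalg.eigvalsh(m)) > -1e-10

    def test_rejects_constant_region(self):
        data = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(ValueError, match="constant"):
            fc(ROITimeSeries(data=data))


class TestFCSimilarity:
    def test_self_similarity_and_linear_relation(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.1
        a[0, 2] = a[2, 0] = 0.2
        a[1, 2] = a[2, 1] = 0.3
        b = np.eye(3)
        b[0, 1] = b[1, 0] = 0.2
        b[0, 2] = b[2, 0] = 0.4
        b[1, 2] = b[2, 1] = 0.6
        assert fc_similarity(FCMatrix(a), FCMatrix(a)) == pytest.approx(1.0)
        assert fc_similarity(FCMatrix(a), FCMatrix(b)) == pytest.approx(1.0)

    def test_unstructured_permutation_near_zero(self, rng):
        sims = []
        for _ in range(100):
            x = rng.standard_normal((60, 8))
            a = np.corrcoef(x.T)
            perm = rng.permutation(8)
            b = a[np.ix_(perm, perm)]
            sims.append(fc_similarity(FCMatrix(a), FCMatrix(b)))
        assert abs(np.mean(sims)) < 0.15

    def test_rejects_ordering_mismatch(self):
        a = FCMatrix(np.eye(2), ordering=["A", "B"])
        b = FCMatrix(np.eye(2), ordering=["B", "A"])
        with pytest.raises(ValueError, match="ordering"):
            fc_similarity(a, b)


class TestPowerSlope:
    def test_white_noise_flat(self, rng):
        slopes = [
            power_slope(rng.standard_normal((2048, 4)), tr_s=0.72)[2]
            for _ in range(100)
        ]
        assert abs(np.mean(slopes)) < 0.15

    def test_recovers_synthesized_one_over_f(self, rng):
        slopes = []
        for _ in range(20):
            n = 4096
            freqs = np.fft.rfftfreq(n, d=0.72)
            amp = np.zeros_like(freqs)
            amp[1:] = freqs[1:] ** (-0.45)  # power ~ f^-0.9
            phases = rng.uniform(0, 2 * np.pi, freqs.size)
            x = np.fft.irfft(amp * np.exp(1j * phases), n=n)
            slopes.append(power_slope(x[:, None], tr_s=0.72)[2])
        assert abs(np.mean(slopes) - 0.9) < 0.1

    def test_pure_sine_rejected_with_warning(self):
        t = np.arange(4096) * 0.72
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        with pytest.warns(RuntimeWarning, match="slope fit rejected"):
            slope = power_slope(x, tr_s=0.72)[2]
        assert np.isnan(slope)

    def test_rejects_unresolvable_band(self, rng):
        with pytest.raises(ValueError, match="bins"):
            power_slope(rng.standard_normal((64, 2)), f_lo=0.01, f_hi=0.012, tr_s=0.72)


class TestPersistence:
    def test_repeats_last_frame(self):
        seg = np.arange(12.0).reshape(4, 3)
        out = persistence_forecast(seg, 3)
        np.testing.assert_array_equal(out, np.tile(seg[-1], (3, 1)))

    def test_ar1_step_one_r2_identity(self, rng):
        """On z-scored AR(1) data, the persistence one-step R^2 is 2*rho - 1."""
        rho = 0.9
        n = 10000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + np.sqrt(1 - rho ** 2) * innov[t]
        x = (x - x.mean()) / x.std()
        act = x[1:][:, None]
        pred = x[:-1][:, None]
        r2 = r2_score_pooled(pred, act)
        assert abs(r2 - (2 * rho - 1)) < 0.02
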