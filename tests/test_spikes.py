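import numpy as np
import pytest
from scipy.optimize import nnls

from caimnet.spikes import (
    DeconvolutionParams,
    build_raster,
    cell_activity_features,
    deconvolution_objective,
    deconvolve_trace,
    estimate_ar_coefficient,
)


def ar_trace(spike_bins, amps, T, gamma):
    s = np.zeros(T)
    for b, a in zip(spike_bins, np.broadcast_to(amps, (len(spike_bins),))):
        s[b] += a
    c = np.empty(T)
    c[0] = s[0]
    for t in range(1, T):
        c[t] = gamma * c[t - 1] + s[t]
    return c


def ar_design(T, gamma):
    A = np.zeros((T, T))
    for t in range(T):
        A[t, : t + 1] = gamma ** np.arange(t, -1, -1)
    return A


class TestEstimateGamma:
    def test_noiseless_ar1_recovered(self, rng):
        bins = rng.integers(0, 4000, 60)
        y = ar_trace(bins, 1.0, 4000, 0.9)
        assert abs(estimate_ar_coefficient(y, 20.0) - 0.9) < 0.02

    def test_white_noise_has_no_structure(self, rng):
        y = rng.normal(0, 1, 5000)
        assert estimate_ar_coefficient(y, 20.0) < 0.1

    def test_noisy_recovery_across_seeds(self):
        errs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            bins = r.integers(0, 8000, 80)
            y = ar_trace(bins, 1.0, 8000, 0.95) + r.normal(0, 0.1, 8000)
            errs.append(abs(estimate_ar_coefficient(y, 20.0) - 0.95))
        assert max(errs) < 0.05

    def test_flat_trace_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            g = estimate_ar_coefficient(np.zeros(500), 20.0, fallback=0.88)
        assert g == 0.88


class TestDeconvolve:
    def test_zero_trace_gives_nothing(self):
        c, s, on = deconvolve_trace(
            np.zeros(100), DeconvolutionParams(gamma=0.9, baseline=0.0)
        )
        assert on.size == 0
        np.testing.assert_allclose(c, 0.0, atol=1e-12)

    def test_single_transient_recovered_at_planted_frame(self):
        y = ar_trace([30], 1.0, 80, 0.9)
        params = DeconvolutionParams(gamma=0.9, lambda_=0.0, s_min=0.3, baseline=0.0)
        c, s, on = deconvolve_trace(y, params)
        assert on.tolist() == [30]
        # exhaustive single-onset oracle: frame 30 is the best placement
        objs = {}
        for b in range(1, 80):
            cb = ar_trace([b], 1.0, 80, 0.9)
            objs[b] = deconvolution_objective(y, cb, 0.9, 0.0)
        assert min(objs, key=objs.get) == 30

    def test_subthreshold_transient_yields_no_onsets(self):
        y = ar_trace([30], 0.2, 80, 0.9)
        params = DeconvolutionParams(gamma=0.9, lambda_=0.0, s_min=0.3, baseline=0.0)
        _, _, on = deconvolve_trace(y, params)
        assert on.size == 0

    def test_noiseless_reconvolution_residual(self, rng):
        bins = np.sort(rng.choice(np.arange(5, 500, 10), 20, replace=False))
        y = ar_trace(bins, 1.0, 500, 0.9)
        params = DeconvolutionParams(gamma=0.9, lambda_=0.0, s_min=0.3, baseline=0.0)
        c, s, on = deconvolve_trace(y, params)
        assert np.max(np.abs(c - y)) < 1e-8
        assert on.tolist() == bins.tolist()

    def test_objective_matches_nnls_oracle(self):
        worst = 0.0
        for seed in range(10):
            r = np.random.default_rng(seed)
            gamma = r.uniform(0.5, 0.95)
            T = int(r.integers(20, 61))
            y = r.normal(0, 0.3, T)
            for amp in r.uniform(0.5, 4.0, r.integers(1, 5)):
                t0 = r.integers(0, T)
                y[t0:] += amp * gamma ** np.arange(T - t0)
            lam = r.uniform(0.5, 5.0)
            params = DeconvolutionParams(
                gamma=gamma, lambda_=lam, s_min=0.0, baseline=0.0
            )
            c, _, _ = deconvolve_trace(y, params)
            obj = deconvolution_objective(y, c, gamma, lam)
            A = ar_design(T, gamma)
            shift = np.full(T, 1 - gamma)
            shift[-1] = 1.0
            s_opt, _ = nnls(A, y - lam * shift, maxiter=10000)
            oracle = deconvolution_objective(y, A @ s_opt, gamma, lam)
            worst = max(worst, abs(obj - oracle) / abs(oracle))
        assert worst < 1e-6

    def test_threshold_is_hard_constraint(self, rng):
        # every reported jump is either (near) zero or at least s_min
        for seed in range(20):
            r = np.random.default_rng(seed)
            T = int(r.integers(20, 80))
            y = r.normal(0, 0.2, T)
            for amp in r.uniform(0.4, 2.0, r.integers(0, 4)):
                t0 = r.integers(1, T)
                y[t0:] += amp * 0.85 ** np.arange(T - t0)
            _, s, _ = deconvolve_trace(
                y,
                DeconvolutionParams(gamma=0.85, lambda_=1.0, s_min=0.3, baseline=0.0),
            )
            assert not np.any((s[1:] > 1e-9) & (s[1:] < 0.3 - 1e-9))

    def test_lambda_monotonicity(self, rng):
        y = ar_trace([20, 60, 110], 1.0, 200, 0.9) + rng.normal(0, 0.1, 200)
        totals = []
        for lam in (0.0, 1.0, 5.0, 20.0):
            _, s, _ = deconvolve_trace(
                y, DeconvolutionParams(gamma=0.9, lambda_=lam, s_min=0.0, baseline=0.0)
            )
            totals.append(s.sum())
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_smin_monotonicity(self, rng):
        y = ar_trace([20, 60, 110], [1.0, 0.5, 0.35], 200, 0.9) + rng.normal(
            0, 0.05, 200
        )
        counts = []
        for smin in (0.1, 0.3, 0.6, 1.2):
            _, _, on = deconvolve_trace(
                y,
                DeconvolutionParams(gamma=0.9, lambda_=0.0, s_min=smin, baseline=0.0),
            )
            counts.append(on.size)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_time_shift_equivariance(self):
        y = ar_trace([40, 90], 1.0, 300, 0.9)
        params = DeconvolutionParams(gamma=0.9, lambda_=0.5, s_min=0.3, baseline=0.0)
        _, _, on0 = deconvolve_trace(y, params)
        k = 7
        y_shift = np.concatenate([np.zeros(k), y[:-k]])
        _, _, on1 = deconvolve_trace(y_shift, params)
        np.testing.assert_array_equal(on1, on0 + k)

    def test_bad_gamma_rejected(self):
        with pytest.raises(ValueError):
            deconvolve_trace(np.zeros(10), DeconvolutionParams(gamma=1.5))


class TestBuildRaster:
    def test_empty_onsets(self):
        raster = build_raster([np.array([])], 20.0, 10.0)
        assert raster.shape == (1, 200)
        assert raster.sum() == 0

    def test_adjacent_frames(self):
        raster = build_raster([np.array([0.0, 0.05])], 20.0, 1.0)
        assert raster[0, 0] == 1 and raster[0, 1] == 1
        assert raster.sum() == 2

    def test_matches_bruteforce_binning(self, rng):
        onsets = [np.sort(rng.uniform(0, 60.0, rng.integers(0, 100))) for _ in range(8)]
        raster = build_raster(onsets, 20.0, 60.0)
        for i, o in enumerate(onsets):
            expected = np.zeros(1200, dtype=int)
            for t in o:
                expected[int(np.floor(t * 20.0))] = 1
            np.testing.assert_array_equal(raster[i], expected)

    def test_out_of_range_onset_rejected(self):
        with pytest.raises(ValueError):
            build_raster([np.array([11.0])], 20.0, 10.0)


class TestCellActivityFeatures:
    def test_worked_example_of_gap_rule(self):
        feats = cell_activity_features(
            np.array([0.0, 0.5, 0.9, 3.0, 3.4]), duration_s=10.0
        )
        assert feats.n_bursts == 2
        np.testing.assert_allclose(feats.spikes_per_burst, [3, 2])
        np.testing.assert_allclose(feats.burst_duration_s, [0.9, 0.4])
        np.testing.assert_allclose(feats.ibi_s, [2.1])
        assert feats.firing_rate_hz == pytest.approx(0.5)
        assert feats.isi_s.size == 4

    def test_no_onsets(self):
        feats = cell_activity_features(np.array([]), duration_s=10.0)
        assert feats.firing_rate_hz == 0.0
        assert feats.n_bursts == 0
        assert feats.burst_duration_s.size == 0

    def test_exact_gap_boundary_excluded(self):
        feats = cell_activity_features(
            np.arange(0.0, 5.0, 1.0), duration_s=10.0, burst_gap_s=1.0
        )
        assert feats.n_bursts == 0

    def test_burst_amplitude_sums_spike_signal(self):
        signal = np.zeros(200)
        signal[[10, 14, 18]] = [1.0, 0.5, 0.25]
        feats = cell_activity_features(
            np.array([0.5, 0.7, 0.9]), duration_s=10.0,
            spike_signal=signal, fs_hz=20.0,
        )
        assert feats.n_bursts == 1
        assert feats.burst_amplitude[0] == pytest.approx(1.75)
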