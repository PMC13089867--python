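"""Gaze preprocessing, epoching, timecourses, and cluster statistics."""

import numpy as np
import pytest
from scipy import stats

from affordmap import gaze as gz
from affordmap.rdm import RDM
from affordmap.simulate import GazeStream


def make_stream(n=5000, hz=1000.0, xl=None, xr=None, blink=None):
    t = np.arange(n) * 1000.0 / hz
    zeros = np.zeros(n)
    return GazeStream(
        t_ms=t,
        xl=zeros.copy() if xl is None else xl,
        yl=zeros.copy(),
        xr=zeros.copy() if xr is None else xr,
        yr=zeros.copy(),
        blink=np.zeros(n, dtype=bool) if blink is None else blink,
        hz=hz,
    )


class TestPreprocess:
    def test_blink_buffer_boundary_inclusive(self):
        blink = np.zeros(5000, dtype=bool)
        blink[1000:1201] = True  # blink spanning [1000, 1200] ms
        clean = gz.preprocess_gaze(make_stream(blink=blink))
        assert np.isnan(clean.x[900])and np.isnan(clean.x[1300])
        assert not np.isnan(clean.x[899]) and not np.isnan(clean.x[1301])

    def test_cyclopean_mean(self):
        xl = np.full(5000, 10.0)
        xr = np.full(5000, 20.0)
        clean = gz.preprocess_gaze(make_stream(xl=xl, xr=xr))
        assert np.allclose(clean.x, 15.0)

    def test_blink_free_stream_untouched(self):
        clean = gz.preprocess_gaze(make_stream())
        assert not np.isnan(clean.x).any()

    def test_fully_masked_rejected(self):
        blink = np.ones(500, dtype=bool)
        with pytest.raises(gz.NoValidSamplesError):
            gz.preprocess_gaze(make_stream(n=500, blink=blink))


class TestEpochs:
    def test_alignment_exact(self):
        x = np.arange(5000, dtype=float)
        clean = gz.preprocess_gaze(make_stream(xl=x, xr=x))
        epochs = gz.epoch_gaze(clean, onsets_s=[2.0], conditions=[1])
        # sample at onset + k ms carries value 2000 + k
        k = np.where(epochs.times_ms == 0)[0][0]
        assert epochs.data[0, k, 0] == 2000.0
        assert epochs.data[0, k + 137, 0] == 2137.0
        assert epochs.data[0, 0, 0] == 1500.0  # -500 ms

    def test_out_of_range_masked(self):
        clean = gz.preprocess_gaze(make_stream(n=1000))
        epochs = gz.epoch_gaze(clean, onsets_s=[0.2], conditions=[1])
        assert epochs.mask[0, 0]  # before recording start
        assert np.isnan(epochs.data[0, 0, 0])


class TestTimecourses:
    def test_constant_trials_unchanged_by_smoothing(self):
        data = np.full((6, 300, 2), 7.0)
        epochs = gz.GazeEpochs(
            data=data,
            mask=np.zeros((6, 300), bool),
            conditions=np.array([2, 2, 2, 3, 3, 3]),
            times_ms=np.arange(300, dtype=float),
            hz=1000.0,
        )
        tcs = gz.condition_timecourses(epochs)
        assert np.allclose(tcs[2], 7.0)

    def test_median_robust_to_outlier_trial(self):
        data = np.zeros((15, 100, 2))
        data[0] = 500.0  # one corrupted trial
        epochs = gz.GazeEpochs(
            data=data,
            mask=np.zeros((15, 100), bool),
            conditions=np.full(15, 2),
            times_ms=np.arange(100, dtype=float),
            hz=1000.0,
        )
        tcs = gz.condition_timecourses(epochs)
        assert np.allclose(tcs[2], 0.0)

    def test_smoothing_kernel_is_truncated_gaussian(self):
        kernel = gz._truncated_gaussian_kernel(4.25, 20.0, 1.0)
        assert len(kernel) == 21  # +-10 ms support at 1 kHz
        assert np.isclose(kernel.sum(), 1.0)
        t = np.arange(-10, 11)
        expected = np.exp(-0.5 * (t / 4.25) ** 2)
        np.testing.assert_allclose(kernel, expected / expected.sum())

    def test_impulse_response_equals_kernel(self):
        data = np.zeros((1, 101, 2))
        data[0, 50, :] = 1.0
        epochs = gz.GazeEpochs(
            data=data,
            mask=np.zeros((1, 101), bool),
            conditions=np.array([2]),
            times_ms=np.arange(101, dtype=float),
            hz=1000.0,
        )
        tcs = gz.condition_timecourses(epochs)
        kernel = gz._truncated_gaussian_kernel(4.25, 20.0, 1.0)
        np.testing.assert_allclose(tcs[2][40:61, 0], kernel, atol=1e-12)


class TestLateralization:
    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=100), rng.normal(size=100)
        np.testing.assert_allclose(
            gz.lateralization_timecourse(a, b),
            -gz.lateralization_timecourse(b, a),
        )

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gz.lateralization_timecourse(np.zeros(10), np.zeros(11))


class TestClusterPermutation:
    def test_zero_data_no_clusters(self):
        res = gz.cluster_permutation_test(np.zeros((8, 200)), n_perm=100, seed=0)
        assert res.clusters == []

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(16, 600)) * 0.5
        data[:, 250:400] += 1.0
        res = gz.cluster_permutation_test(data, n_perm=500, seed=1)
        sig = res.significant
        assert len(sig) >= 1
        big = max(sig, key=lambda c: c.mass)
        assert big.start_ms < 300 and big.end_ms > 350

    def test_p_never_zero(self):
        data = np.ones((10, 50)) + np.random.default_rng(0).normal(size=(10, 50)) * 0.01
        res = gz.cluster_permutation_test(data, n_perm=200, seed=2)
        assert all(c.p >= 1 / 201 for c in res.clusters)

    def test_default_threshold_is_t_crit(self):
        data = np.random.default_rng(1).normal(size=(12, 100))
        res = gz.cluster_permutation_test(data, n_perm=50, seed=0)
        assert np.isclose(res.threshold, stats.t.ppf(0.95, 11))

    def test_agrees_with_mne(self):
        from mne.stats import permutation_cluster_1samp_test

        rng = np.random.default_rng(7)
        data = rng.normal(size=(14, 300))
        data[:, 100:160] += 0.9
        ours = gz.cluster_permutation_test(data, n_perm=3000, seed=5)
        thr = stats.t.ppf(0.95, 13)
        _, clusters, pvals, _ = permutation_cluster_1samp_test(
            data, threshold=thr, n_permutations=3000, tail=1,
            seed=11, out_type="indices", verbose=False,
        )
        mne_windows = sorted((int(c[0][0]), int(c[0][-1])) for c in clusters)
        our_windows = sorted((int(c.start_ms), int(c.end_ms)) for c in ours.clusters)
        assert mne_windows == our_windows
        our_p = {(int(c.start_ms), int(c.end_ms)): c.p for c in ours.clusters}
        for c, p in zip(clusters, pvals):
            w = (int(c[0][0]), int(c[0][-1]))
            assert abs(our_p[w] - p) < 0.03  # permutation noise


class TestEffectSizes:
    def test_constant_diff_median(self):
        diff = np.full(3001, 4.2)
        times = np.arange(-500, 2501, dtype=float)
        assert gz.cluster_median_shift(diff, times, (899, 1757)) == pytest.approx(4.2)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            gz.cluster_median_shift(np.zeros(100), np.arange(100.0), (500, 600))

    def test_window_median_lateralization_single_trials(self):
        times = np.arange(0, 3000, 100, dtype=float)  # 10 Hz-ish sampling
        x = np.vstack([np.full(len(times), 12.0), np.full(len(times), 2.0)])
        out = gz.window_median_lateralization(
            x, conditions=np.array([2, 3]), times_ms=times,
            window_center_ms=1328.0, window_s=1.0,
        )
        assert out[2] == 12.0 and out[3] == 2.0 and out["difference"] == 10.0

    def test_paired_test_null(self):
        rng = np.random.default_rng(0)
        subs = [
            {2: rng.normal(), 3: rng.normal()} for _ in range(30)
        ]
        res = gz.paired_lateralization_test(subs)
        assert 0.0 < res["p"] < 1.0 and res["df"] == 29


class TestLinking:
    def test_brain_gaze_constructed_relation(self, rng):
        rdms, shifts = [], []
        for k in range(10):
            v = rng.random(6) + 0.2
            rdms.append(RDM.from_vector(v))
            shifts.append(RDM.from_vector(v).normalized("rms").entry(2, 3))
        res = gz.brain_gaze_link(rdms, shifts)
        assert res["r"] == pytest.approx(1.0)

    def test_normalization_scale_invariance(self, rng):
        v = rng.random(6) + 0.2
        a = RDM.from_vector(v).normalized("rms").entry(2, 3)
        b = RDM.from_vector(10 * v).normalized("rms").entry(2, 3)
        assert np.isclose(a, b)

    def test_performance_correlation_linear(self):
        shifts = np.array([1.0, 2, 3, 4, 5])
        acc = 0.5 + 0.08 * shifts
        res = gz.performance_correlation(shifts, acc)
        assert res["r"] == pytest.approx(1.0)

    def test_performance_corr_affine_invariant(self, rng):
        shifts = rng.normal(size=8)
        acc = rng.random(8)
        r1 = gz.performance_correlation(shifts, acc)["r"]
        r2 = gz.performance_correlation(shifts, 100 * acc)["r"]
        assert np.isclose(r1, r2)
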