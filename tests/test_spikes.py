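"""Spike detection rules, firing statistics, spike-triggered averages."""

import numpy as np
import pytest

from mernav.simulate import spike_template
from mernav.spikes import (aggregate_patient_metrics, cv_isi, detect_spikes,
                           estimate_noise_sd, firing_rate,
                           remove_outliers_iqr, spike_triggered_average,
                           spike_triggered_average_multi)

from _oracles import brute_force_spike_detection
from conftest import FS_TEST


def _place(times, fs=FS_TEST, dur=4.0, amp=10.0, noise_sd=1.0, seed=0):
    """Noise trace with biphasic waveforms whose peaks sit at `times`."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sd, int(dur * fs))
    w, peak = spike_template(fs)
    for t in times:
        start = int(round(t * fs)) - peak
        x[start:start + w.size] += amp * w[:max(0, min(w.size, x.size - start))]
    return x


class TestNoiseSd:
    def test_gaussian_noise(self):
        x = np.random.default_rng(1).normal(0, 1.0, int(4 * FS_TEST))
        assert estimate_noise_sd(x) == pytest.approx(1.0, abs=0.02)

    def test_robust_to_spikes(self):
        x = _place(np.linspace(0.2, 3.8, 10), amp=20.0, seed=2)
        clean = np.random.default_rng(2).normal(0, 1.0, x.size)
        robust = estimate_noise_sd(x)
        assert abs(robust - estimate_noise_sd(clean)) / 1.0 < 0.02
        # the plain SD is visibly inflated by the same spikes
        assert estimate_noise_sd(x, "std") > robust + 0.02

    def test_degenerate(self):
        assert estimate_noise_sd(np.zeros(100)) == 0.0
        with pytest.raises(ValueError):
            estimate_noise_sd([])


class TestDetection:
    # Constructed-example tests hand the detector a deliberately conservative
    # noise SD (1.75, i.e. a 7-sigma threshold on the unit-SD noise): raw
    # noise cannot cross it over 4 s and the waveform troughs (4.9 + noise)
    # stay below it too, so only the placed peaks (amplitude 10) produce
    # candidates and the rule tracing is exact.
    # Realistic thresholds are exercised by the brute-force equivalence test
    # below and by the firing-rate recovery suite.

    def test_three_clean_spikes(self):
        times = [0.5, 1.5, 2.5]
        r = detect_spikes(_place(times), FS_TEST, noise_sd=1.75)
        assert r.n_spikes == 3
        assert np.allclose(r.spike_times_s, times, atol=0.2e-3)
        assert r.firing_rate_hz == pytest.approx(3 / 4.0)

    def test_refractory_suppresses_1ms_pair(self):
        r = detect_spikes(_place([1.0, 1.001]), FS_TEST, noise_sd=1.75)
        assert r.n_spikes == 1
        assert abs(r.spike_times_s[0] - 1.0) < 0.2e-3

    def test_exclusion_removes_earlier_of_1p8ms_pair(self):
        r = detect_spikes(_place([1.0, 1.0018]), FS_TEST, noise_sd=1.75)
        assert r.n_spikes == 1
        assert r.n_excluded_collision == 1
        # survivor is the later spike: the earlier one had a spike in its
        # +2 ms window, the later one has none in its -1 ms window
        assert abs(r.spike_times_s[0] - 1.0018) < 0.2e-3

    def test_drop_both_policy(self):
        r = detect_spikes(_place([1.0, 1.0018]), FS_TEST, noise_sd=1.75,
                          collision_policy="drop_both")
        assert r.n_spikes == 0

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(1000), FS_TEST)

    def test_min_isi_respects_refractory(self):
        x = _place(np.arange(0.1, 3.9, 0.02), seed=3)  # 50 Hz train
        r = detect_spikes(x, FS_TEST, noise_sd=1.0)
        if r.n_spikes > 1:
            assert np.diff(r.spike_times_s).min() >= 1.5e-3 - 1e-9

    def test_matches_brute_force_on_random_signals(self):
        """Oracle equivalence of the three detection rules (small scale;
        the acceptance suite runs the 200-signal version)."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(200, 4000))
            x = rng.normal(0, 1.0, n)
            for _ in range(rng.integers(0, 8)):
                i = int(rng.integers(5, n - 5))
                x[i] += rng.uniform(4.0, 12.0) * rng.choice([-1.0, 1.0])
            got = detect_spikes(x, FS_TEST, noise_sd=1.0)
            expected = brute_force_spike_detection(x, FS_TEST, sigma=1.0)
            assert np.array_equal(np.round(got.spike_times_s * FS_TEST).astype(int),
                                  expected)


class TestFiringStatistics:
    def test_firing_rate(self):
        assert firing_rate(np.arange(40), 4.0) == 10.0
        assert firing_rate([], 4.0) == 0.0
        with pytest.raises(ValueError):
            firing_rate([1.0], 0.0)

    def test_cv_isi_regular_train(self):
        assert cv_isi(np.arange(0, 1, 0.01)) == pytest.approx(0.0, abs=1e-12)

    def test_cv_isi_poisson_limit(self):
        rng = np.random.default_rng(4)
        t = np.cumsum(rng.exponential(0.01, 3000))
        assert cv_isi(t) == pytest.approx(1.0, abs=0.1)

    def test_cv_isi_undefined_below_three_spikes(self):
        assert np.isnan(cv_isi([0.1, 0.2]))

    def test_iqr_outlier_removal(self):
        kept, removed = remove_outliers_iqr(list(range(1, 11)) + [100])
        assert removed.tolist() == [100.0]
        assert kept.size == 10
        kept, removed = remove_outliers_iqr([5.0] * 6)
        assert removed.size == 0
        kept, removed = remove_outliers_iqr(list(range(1, 11)) + [100],
                                            multiplier=np.inf)
        assert removed.size == 0
        with pytest.raises(ValueError):
            remove_outliers_iqr([1.0, 2.0, 3.0])


class TestAggregation:
    def _result(self, times, dur=4.0):
        times = np.asarray(times, dtype=float)
        return detect_spikes(_place(times, dur=dur), FS_TEST, noise_sd=1.0)

    def test_single_site_methods_agree(self):
        r = self._result([0.5, 1.0, 1.5, 2.0, 2.5])
        m = aggregate_patient_metrics([r])
        pooled = m.by_method["pooled_isi"]
        mean_sites = m.by_method["mean_of_sites"]
        assert pooled[0] == pytest.approx(mean_sites[0])
        assert pooled[1] == pytest.approx(mean_sites[1], rel=1e-6)

    def test_homogeneous_sites_agree(self):
        rng = np.random.default_rng(11)
        results = []
        for s in range(8):
            t = np.sort(rng.uniform(0.2, 3.8, 40))
            t = t[np.r_[True, np.diff(t) > 0.004]]
            results.append(self._result(t))
        m = aggregate_patient_metrics(results)
        r_pooled = m.by_method["pooled_isi"][0]
        r_mean = m.by_method["mean_of_sites"][0]
        assert r_pooled == pytest.approx(r_mean, rel=0.05)

    def test_empty_patient_flagged(self):
        m = aggregate_patient_metrics([])
        assert not m.defined and np.isnan(m.firing_rate_hz)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            aggregate_patient_metrics([], method="median_of_sites")


class TestSta:
    def test_spikes_at_sine_peaks(self):
        fs = 20_000.0
        dur = 30.0
        t = np.arange(int(dur * fs)) / fs
        lfp = np.sin(2 * np.pi * 5.0 * t)
        x = lfp + 0.01 * np.random.default_rng(0).standard_normal(t.size)
        peaks = np.arange(0.05, dur - 0.05, 0.2)  # crests of the 5 Hz sine
        sta = spike_triggered_average(peaks, x, fs, "lfp_1_70")
        assert sta.trace.size == 3001
        assert sta.lags_s[0] == -1.0 and sta.lags_s[-1] == 2.0
        center = np.abs(sta.lags_s) <= 0.11
        assert sta.lags_s[center][np.argmax(sta.trace[center])] == pytest.approx(0.0, abs=2e-3)
        # the average is itself a 5 Hz oscillation
        ref = np.cos(2 * np.pi * 5.0 * sta.lags_s)
        corr = np.corrcoef(sta.trace, ref)[0, 1]
        assert corr > 0.99

    def test_unlocked_spikes_shrink_with_n(self):
        fs = 20_000.0
        rng = np.random.default_rng(5)
        dur = 40.0
        x = rng.standard_normal(int(dur * fs))
        all_spikes = np.sort(rng.uniform(1.1, dur - 2.1, 3000))
        small = spike_triggered_average(all_spikes[:100], x, fs, "lfp_1_70")
        large = spike_triggered_average(all_spikes, x, fs, "lfp_1_70")
        ratio = np.abs(small.trace).max() / np.abs(large.trace).max()
        expected = np.sqrt(3000 / 100)
        assert expected / 2.5 < ratio < expected * 2.5

    def test_beta_band_sta_period(self):
        fs = 20_000.0
        dur = 30.0
        t = np.arange(int(dur * fs)) / fs
        x = np.sin(2 * np.pi * 20.0 * t) + \
            0.05 * np.random.default_rng(1).standard_normal(t.size)
        locked = np.arange(0.0125, dur - 0.05, 0.05)  # 20 Hz crests
        sta = spike_triggered_average(locked, x, fs, "beta_13_30")
        spec = np.abs(np.fft.rfft(sta.trace))
        freqs = np.fft.rfftfreq(sta.trace.size, 1 / 1000.0)
        assert freqs[np.argmax(spec)] == pytest.approx(20.0, abs=0.5)

    def test_window_bounds_and_errors(self):
        fs = 20_000.0
        x = np.random.default_rng(2).standard_normal(int(4 * fs))
        # only spikes with a full [-1, +2] s window are used
        sta = spike_triggered_average([0.5, 1.5, 3.5], x, fs, "lfp_1_70")
        assert sta.n_spikes_used == 1 and sta.n_spikes_skipped == 2
        with pytest.raises(ValueError, match="window"):
            spike_triggered_average([0.1], x, fs, "lfp_1_70")
        with pytest.raises(ValueError, match="band"):
            spike_triggered_average([1.5], x, fs, "theta")

    def test_multi_record_accumulation(self):
        fs = 20_000.0
        rng = np.random.default_rng(3)
        pairs = [(np.array([1.5]), rng.standard_normal(int(4 * fs)))
                 for _ in range(3)]
        sta = spike_triggered_average_multi(pairs, fs, "lfp_1_70")
        assert sta.n_spikes_used == 3
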