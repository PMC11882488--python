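"""Multiunit spike detection, firing statistics and spike-triggered averages.

Detection follows a three-rule scheme on the 300–3000 Hz band-passed signal:

1. candidate events are local extrema whose absolute amplitude crosses
   ``k`` times a robust estimate of the noise SD (both polarities);
2. a 1.5 ms refractory pass suppresses candidates too close after an
   accepted one;
3. a collision pass removes any surviving spike that has another surviving
   spike within (-1 ms, +2 ms) around it — with the refractory pass already
   applied this removes the earlier member of close pairs (the later one
   falls inside its +2 ms window), evaluated against the pre-pass set.

Firing rate is spike count over duration; CV-ISI is the sample SD of
inter-spike intervals over their mean (undefined below 3 spikes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

#: Bands available for spike-triggered averaging of the field potential.
STA_BANDS: dict[str, tuple[float, float]] = {
    "lfp_1_70": (1.0, 70.0),
    "beta_13_30": (13.0, 30.0),
}


def bandpass_spike(signal: Sequence[float], fs: float,
                   low: float = 300.0, high: float = 3000.0) -> np.ndarray:
    """Zero-phase 300–3000 Hz band-pass isolating spike waveforms."""
    from .features import bandpass_spiking
    return bandpass_spiking(signal, fs, low=low, high=high)


def estimate_noise_sd(filtered_signal: Sequence[float],
                      method: str = "robust") -> float:
    """Noise SD of a filtered trace.

    "robust" uses median(|x|)/0.6745 (the normal-consistent median absolute
    deviation about zero), which large, sparse spikes barely perturb;
    "std" is the plain standard deviation, kept for sensitivity analysis.
    """
    x = np.asarray(filtered_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if method == "robust":
        return float(np.median(np.abs(x)) / 0.6745)
    if method == "std":
        return float(x.std())
    raise ValueError(f"unknown noise estimator {method!r}")


@dataclass
class SpikeTrainResult:
    """Detected spike train of one site."""

    spike_times_s: np.ndarray
    duration_s: float
    n_detected_raw: int
    n_excluded_collision: int
    firing_rate_hz: float
    cv_isi: float  # nan when fewer than 3 spikes survive
    noise_sd: float
    trajectory_id: str | None = None
    site_index: int | None = None

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    @property
    def cv_defined(self) -> bool:
        return bool(np.isfinite(self.cv_isi))


def _candidate_extrema(x: np.ndarray, threshold: float) -> np.ndarray:
    """Local extrema of |x| at or above threshold (rule 1)."""
    a = np.abs(x)
    if a.size < 3:
        return np.empty(0, dtype=int)
    mid = a[1:-1]
    mask = (mid >= threshold) & (mid >= a[:-2]) & (mid > a[2:])
    return np.nonzero(mask)[0] + 1


def _refractory_pass(idx: np.ndarray, ref_samples: int) -> np.ndarray:
    """Suppress candidates within the refractory window after an accepted one."""
    kept = []
    last = -10 ** 12
    for i in idx:
        if i - last >= ref_samples:
            kept.append(i)
            last = i
    return np.asarray(kept, dtype=int)


def _collision_pass(idx: np.ndarray, pre_samples: int, post_samples: int,
                    policy: str = "drop_earlier") -> tuple[np.ndarray, int]:
    """Remove spikes with a neighbor inside the open (-pre, +post) window.

    Removal is evaluated against the pre-pass set simultaneously: under the
    default policy a spike goes when any *other* pre-pass spike lies strictly
    within its window.  "drop_both" removes both members of any pair closer
    than the post window.
    """
    n = idx.size
    if n < 2:
        return idx, 0
    remove = np.zeros(n, dtype=bool)
    gaps = np.diff(idx)
    if policy == "drop_earlier":
        # neighbor checks suffice: windows are contiguous in time
        remove[:-1] |= gaps < post_samples   # later spike in my +post window
        remove[1:] |= gaps < pre_samples     # earlier spike in my -pre window
    elif policy == "drop_both":
        close = gaps < post_samples
        remove[:-1] |= close
        remove[1:] |= close
    else:
        raise ValueError(f"unknown collision policy {policy!r}")
    return idx[~remove], int(remove.sum())


def detect_spikes(filtered_signal: Sequence[float], fs: float, k: float = 4.0,
                  refractory_ms: float = 1.5, pre_ms: float = 1.0,
                  post_ms: float = 2.0, noise_sd: float | None = None,
                  noise_estimator: str = "robust",
                  collision_policy: str = "drop_earlier",
                  trajectory_id: str | None = None,
                  site_index: int | None = None) -> SpikeTrainResult:
    """Threshold/refractory/collision spike detection on a filtered trace."""
    x = np.asarray(filtered_signal, dtype=float)
    sigma = estimate_noise_sd(x, noise_estimator) if noise_sd is None else float(noise_sd)
    if sigma == 0:
        raise ValueError("noise SD is zero; cannot set a threshold")
    cand = _candidate_extrema(x, k * sigma)
    ref = int(round(refractory_ms * 1e-3 * fs))
    kept = _refractory_pass(cand, ref)
    final, n_excl = _collision_pass(
        kept, int(round(pre_ms * 1e-3 * fs)), int(round(post_ms * 1e-3 * fs)),
        policy=collision_policy)
    duration = x.size / fs
    times = final / fs
    return SpikeTrainResult(
        spike_times_s=times, duration_s=duration,
        n_detected_raw=int(cand.size), n_excluded_collision=n_excl,
        firing_rate_hz=firing_rate(times, duration), cv_isi=cv_isi(times),
        noise_sd=sigma, trajectory_id=trajectory_id, site_index=site_index)


def firing_rate(spike_times: Sequence[float], duration_s: float) -> float:
    """Total number of spikes divided by the recording duration."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return len(spike_times) / duration_s


def cv_isi(spike_times: Sequence[float]) -> float:
    """Coefficient of variation of inter-spike intervals (sample SD / mean).

    Returns nan (undefined) with fewer than 3 spikes.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 3:
        return float("nan")
    isi = np.diff(t)
    mean = isi.mean()
    if mean <= 0:
        return float("nan")
    return float(np.std(isi, ddof=1) / mean)


@dataclass
class PatientMetrics:
    """Patient-level firing rate and CV-ISI under both aggregation rules."""

    firing_rate_hz: float
    cv_isi: float
    method: str
    by_method: dict[str, tuple[float, float]]
    n_sites: int
    defined: bool = True


def aggregate_patient_metrics(site_results: Sequence[SpikeTrainResult],
                              method: str = "pooled_isi") -> PatientMetrics:
    """Combine per-site spike trains into per-patient rate and CV-ISI.

    "pooled_isi" pools spike counts/durations and all within-site ISIs;
    "mean_of_sites" averages the per-site estimates.  Both are computed and
    returned; the requested one populates the headline fields.
    """
    if method not in ("pooled_isi", "mean_of_sites"):
        raise ValueError(f"unknown aggregation method {method!r}")
    results = list(site_results)
    if not results:
        return PatientMetrics(float("nan"), float("nan"), method,
                              {"pooled_isi": (float("nan"), float("nan")),
                               "mean_of_sites": (float("nan"), float("nan"))},
                              0, defined=False)
    total_spikes = sum(r.n_spikes for r in results)
    total_dur = sum(r.duration_s for r in results)
    pooled_rate = total_spikes / total_dur
    isis = [np.diff(r.spike_times_s) for r in results if r.n_spikes >= 2]
    pooled = np.concatenate(isis) if isis else np.empty(0)
    if pooled.size >= 2 and pooled.mean() > 0:
        pooled_cv = float(np.std(pooled, ddof=1) / pooled.mean())
    else:
        pooled_cv = float("nan")
    site_rates = [r.firing_rate_hz for r in results]
    site_cvs = [r.cv_isi for r in results if r.cv_defined]
    mean_rate = float(np.mean(site_rates))
    mean_cv = float(np.mean(site_cvs)) if site_cvs else float("nan")
    by = {"pooled_isi": (pooled_rate, pooled_cv),
          "mean_of_sites": (mean_rate, mean_cv)}
    rate, cv = by[method]
    return PatientMetrics(rate, cv, method, by, len(results))


def remove_outliers_iqr(values: Sequence[float], multiplier: float = 1.5,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, removed) by interquartile-range fences.

    Quartiles use linear interpolation; values outside
    [Q1 - m*IQR, Q3 + m*IQR] are removed.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for IQR outlier removal")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    keep = (v >= lo) & (v <= hi)
    return v[keep], v[~keep]


# ---------------------------------------------------------------------------
# spike-triggered averaging
# ---------------------------------------------------------------------------

@dataclass
class StaResult:
    """Spike-triggered average of the (band-limited) field potential."""

    lags_s: np.ndarray
    trace: np.ndarray
    n_spikes_used: int
    n_spikes_skipped: int
    band: str


def _lfp_trace(wideband: np.ndarray, fs: float, band: tuple[float, float],
               out_fs: float) -> np.ndarray:
    """Zero-phase band-pass then decimation to the STA sampling rate."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, wideband)
    q = int(round(fs / out_fs))
    if q < 1 or abs(fs / q - out_fs) > 1e-6:
        raise ValueError(f"fs={fs} not an integer multiple of out_fs={out_fs}")
    return y[::q]


def _sta_accumulate(spike_times: Sequence[float], lfp: np.ndarray,
                    out_fs: float, n_pre: int, n_post: int,
                    acc: np.ndarray) -> tuple[int, int]:
    used = skipped = 0
    for t in np.asarray(spike_times, dtype=float):
        c = int(round(t * out_fs))
        if c - n_pre < 0 or c + n_post >= lfp.size:
            skipped += 1
            continue
        acc += lfp[c - n_pre:c + n_post + 1]
        used += 1
    return used, skipped


def spike_triggered_average(spike_times: Sequence[float],
                            wideband: Sequence[float], fs: float, band: str,
                            pre_s: float = 1.0, post_s: float = 2.0,
                            out_fs: float = 1000.0) -> StaResult:
    """Average LFP in a window from ``pre_s`` before to ``post_s`` after each
    spike (defaults: -1 s to +2 s, 1 kHz output rate).

    The wideband signal is band-passed with a zero-phase (non-causal)
    4th-order Butterworth filter — "lfp_1_70" or "beta_13_30" — and decimated
    before windowing.  Spikes whose window exceeds the record bounds are
    skipped and counted; raises if no complete window remains.
    """
    return spike_triggered_average_multi(
        [(spike_times, wideband)], fs, band,
        pre_s=pre_s, post_s=post_s, out_fs=out_fs)


def spike_triggered_average_multi(pairs, fs: float, band: str,
                                  pre_s: float = 1.0, post_s: float = 2.0,
                                  out_fs: float = 1000.0) -> StaResult:
    """STA accumulated over multiple (spike_times, wideband) records.

    Windows never span record boundaries, matching analysis of a
    site-by-site recording protocol.
    """
    if band not in STA_BANDS:
        raise ValueError(f"unknown STA band {band!r}; choose from {sorted(STA_BANDS)}")
    n_pre = int(round(pre_s * out_fs))
    n_post = int(round(post_s * out_fs))
    acc = np.zeros(n_pre + n_post + 1)
    used = skipped = 0
    for spike_times, wideband in pairs:
        lfp = _lfp_trace(np.asarray(wideband, dtype=float), fs,
                         STA_BANDS[band], out_fs)
        u, s = _sta_accumulate(spike_times, lfp, out_fs, n_pre, n_post, acc)
        used += u
        skipped += s
    if used == 0:
        raise ValueError("no spike window fits inside the record bounds")
    lags = np.arange(-n_pre, n_post + 1) / out_fs
    return StaResult(lags_s=lags, trace=acc / used, n_spikes_used=used,
                     n_spikes_skipped=skipped, band=band)
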