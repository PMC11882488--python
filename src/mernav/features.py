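"""Per-site navigation features: RMS, normalized RMS, envelope spectra.

The multiunit "envelope" spectrum is the power spectral density of the
rectified 300–6000 Hz band-passed signal, normalized to total power so every
value is a fraction of the site's power — a measure insensitive to overall
amplitude changes along the trajectory.  Spectra use Welch's method with 3-s
Hann segments (1/3 Hz resolution on a 4-s record) and 50 % overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import interp1d

from .borders import StnAnnotation
from .config import BANDS


def bandpass_spiking(signal: Sequence[float], fs: float,
                     low: float = 300.0, high: float = 6000.0,
                     order: int = 4) -> np.ndarray:
    """Zero-phase band-pass (forward-backward 4th-order Butterworth).

    ``high`` is clipped to 0.45*fs with a warning when the sampling rate
    cannot support it.  Output length equals input length.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if fs <= 2 * high:
        high = 0.45 * fs
        warnings.warn(f"band edge clipped to {high:.0f} Hz for fs={fs:.0f} Hz",
                      stacklevel=2)
    if low >= high:
        raise ValueError(f"invalid band ({low}, {high}) at fs={fs}")
    if x.size < 12 * order:  # filtfilt needs padding beyond ~3x the order
        raise ValueError(f"signal too short to filter ({x.size} samples)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def compute_rms(signal: Sequence[float]) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute RMS of an empty signal")
    return float(np.sqrt(np.mean(x ** 2)))


def normalize_rms(site_rms: Sequence[float], n_baseline: int = 5) -> np.ndarray:
    """Each site RMS divided by the mean RMS of the first baseline sites.

    The baseline sites sit well above the STN (typically internal capsule),
    so NRMS ~ 1 before entry and rises inside the nucleus.
    """
    r = np.asarray(site_rms, dtype=float)
    if r.size < n_baseline:
        raise ValueError(f"need at least {n_baseline} sites, got {r.size}")
    base = r[:n_baseline].mean()
    if base <= 0:
        raise ValueError("baseline RMS mean is zero")
    return r / base


def compute_site_psd(signal: Sequence[float], fs: float,
                     resolution_hz: float = 1.0 / 3.0,
                     fmax: float | None = 200.0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized envelope power spectrum of a band-passed spiking signal.

    Rectifies (absolute value), removes the mean, and estimates the spectrum
    by Welch's method with segments of 1/resolution_hz seconds, Hann window,
    50 % overlap.  Values are divided by total power over the full computed
    range, so they are fractions of total power; bins up to ``fmax`` are
    returned (all bins when fmax is None).
    """
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(fs / resolution_hz))
    if x.size < nperseg:
        raise ValueError(
            f"signal shorter than one spectral segment ({x.size} < {nperseg})")
    env = np.abs(x)
    env = env - env.mean()
    freqs, pxx = sps.welch(env, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant")
    total = pxx.sum()
    if total <= 0:
        raise ValueError("degenerate signal: zero envelope power")
    frac = pxx / total
    if fmax is not None:
        keep = freqs <= fmax + 1e-9
        freqs, frac = freqs[keep], frac[keep]
    return freqs, frac


def band_power(freqs: np.ndarray, psd: np.ndarray,
               band: tuple[float, float]) -> float:
    """Fraction of total power in [low, high): sum of the covered PSD bins."""
    low, high = band
    if not 0 <= low < high:
        raise ValueError(f"invalid band {band}")
    if low >= freqs[-1] + 1e-9:
        raise ValueError(f"band {band} outside computed range "
                         f"(max {freqs[-1]:.1f} Hz)")
    mask = (freqs >= low) & (freqs < high)
    return float(psd[mask].sum())


@dataclass
class TrajectoryFeatures:
    """Per-site features of one trajectory (ordered by advance)."""

    trajectory_id: str
    group: str
    depths_mm: np.ndarray
    rms: np.ndarray
    nrms: np.ndarray
    freqs: np.ndarray
    psd: np.ndarray  # (n_sites, n_bins), fractions of total power
    band_powers: pd.DataFrame = field(repr=False)  # one column per band

    @property
    def n_sites(self) -> int:
        return int(self.depths_mm.size)

    def table(self) -> pd.DataFrame:
        """Flat per-site table (CSV-friendly)."""
        df = pd.DataFrame({
            "trajectory_id": self.trajectory_id,
            "site_index": np.arange(self.n_sites),
            "depth_mm": self.depths_mm,
            "rms": self.rms,
            "nrms": self.nrms,
        })
        return pd.concat([df, self.band_powers.reset_index(drop=True)], axis=1)


def extract_trajectory_features(recording, *,
                                spiking_band: tuple[float, float] = (300.0, 6000.0),
                                resolution_hz: float = 1.0 / 3.0,
                                fmax: float = 200.0,
                                bands: Mapping[str, tuple[float, float]] | None = None,
                                n_baseline: int = 5) -> TrajectoryFeatures:
    """RMS/NRMS, envelope PSD and band powers for every site of a recording."""
    if bands is None:
        bands = BANDS
    fs = recording.sampling_rate_hz
    rms_list = []
    psd_rows = []
    freqs = None
    for sig in recording.signals:
        filt = bandpass_spiking(sig, fs, *spiking_band)
        rms_list.append(compute_rms(filt))
        freqs, frac = compute_site_psd(filt, fs, resolution_hz=resolution_hz,
                                       fmax=fmax)
        psd_rows.append(frac)
    rms = np.asarray(rms_list)
    nrms = normalize_rms(rms, n_baseline=n_baseline)
    psd = np.vstack(psd_rows)
    bp = pd.DataFrame({name: [band_power(freqs, row, b) for row in psd]
                       for name, b in bands.items()})
    return TrajectoryFeatures(
        trajectory_id=recording.trajectory_id, group=recording.group,
        depths_mm=recording.depths_mm.copy(), rms=rms, nrms=nrms,
        freqs=freqs, psd=psd, band_powers=bp)


def build_depth_spectrogram(psd: np.ndarray) -> np.ndarray:
    """Depth x frequency matrix in percent of total power, rows ordered by
    advance direction."""
    return 100.0 * np.atleast_2d(np.asarray(psd, dtype=float))


def normalize_depth_axis(depths: Sequence[float], values: np.ndarray,
                         annotation: StnAnnotation, n_grid: int = 100,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Resample features onto the normalized depth axis [-0.5, 1].

    STN entry maps to 0 and exit to 1; the pre-entry segment of physical
    length stn_length/2 maps to [-0.5, 0).  ``values`` may be 1-D (one value
    per site) or 2-D (sites x frequency); interpolation is linear along the
    site axis.  A pre-segment shorter than half the STN length is truncated
    (edge-held) with a warning.
    """
    d = np.asarray(depths, dtype=float)
    length = annotation.entry_depth_mm - annotation.exit_depth_mm
    if length <= 0:
        raise ValueError("annotation has non-positive STN length")
    u = (annotation.entry_depth_mm - d) / length
    grid = np.linspace(-0.5, 1.0, n_grid)
    if u.min() > -0.5 + 1e-9:
        warnings.warn("pre-STN segment shorter than half the STN length; "
                      "edge values held constant", stacklevel=2)
    vals = np.asarray(values, dtype=float)
    fill = (vals[0], vals[-1]) if vals.ndim == 1 else (vals[0, :], vals[-1, :])
    f = interp1d(u, vals, axis=0, bounds_error=False, fill_value=fill,
                 assume_sorted=True)
    return grid, f(grid)
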