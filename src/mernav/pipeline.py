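"""Stage functions tying the modules into the full analysis pipeline.

Each stage is a pure function of (inputs, config): feature extraction per
trajectory, border annotation, spike metrics, per-trajectory summaries and
the cohort-level group comparison.  The CLI and the acceptance script are
thin wrappers around these.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .borders import StnAnnotation, annotate_trajectory
from .config import AnalysisConfig
from .features import TrajectoryFeatures, extract_trajectory_features, normalize_depth_axis
from .simulate import TrajectoryRecording
from .spikes import (SpikeTrainResult, aggregate_patient_metrics,
                     bandpass_spike, detect_spikes, remove_outliers_iqr)
from .stats import (GroupComparison, TrajectorySummary, compare_groups,
                    group_average_curves, percent_motor, summarize_trajectory)


def features_stage(recording: TrajectoryRecording,
                   config: AnalysisConfig | None = None) -> TrajectoryFeatures:
    config = config or AnalysisConfig()
    return extract_trajectory_features(
        recording, spiking_band=config.spiking_band_hz,
        resolution_hz=config.psd_resolution_hz, fmax=config.psd_fmax_hz,
        bands=config.bands, n_baseline=config.n_baseline_sites)


def borders_stage(tf: TrajectoryFeatures,
                  config: AnalysisConfig | None = None) -> Optional[StnAnnotation]:
    config = config or AnalysisConfig()
    return annotate_trajectory(
        tf.nrms, tf.depths_mm,
        beta_power=tf.band_powers["beta"].to_numpy(),
        delta_power=tf.band_powers["delta"].to_numpy(),
        threshold=config.nrms_entry_threshold,
        min_run=config.entry_min_run,
        contrast_floor=config.changepoint_contrast_floor,
        fallback_fraction=config.motor_fallback_fraction)


def spikes_stage(recording: TrajectoryRecording, annotation: StnAnnotation,
                 config: AnalysisConfig | None = None) -> list[SpikeTrainResult]:
    """Spike detection on every STN site (entry..exit) of a trajectory."""
    config = config or AnalysisConfig()
    fs = recording.sampling_rate_hz
    results = []
    for k in range(annotation.entry_index, annotation.exit_index + 1):
        filt = bandpass_spike(recording.signals[k], fs,
                              *config.spike_band_hz)
        results.append(detect_spikes(
            filt, fs, k=config.spike_threshold_sd,
            refractory_ms=config.refractory_ms,
            pre_ms=config.exclusion_pre_ms, post_ms=config.exclusion_post_ms,
            noise_estimator=config.noise_sd_estimator,
            collision_policy=config.collision_policy,
            trajectory_id=recording.trajectory_id, site_index=k))
    return results


def summaries_stage(features: Mapping[str, TrajectoryFeatures],
                    annotations: Mapping[str, Optional[StnAnnotation]],
                    config: AnalysisConfig | None = None,
                    ) -> list[TrajectorySummary]:
    config = config or AnalysisConfig()
    out = []
    for tid, tf in features.items():
        ann = annotations.get(tid)
        if ann is None or "degenerate" in ann.flags:
            continue
        out.append(summarize_trajectory(tf, ann, n_grid=config.n_grid))
    return out


def grid_curves(features: Mapping[str, TrajectoryFeatures],
                annotations: Mapping[str, Optional[StnAnnotation]],
                config: AnalysisConfig | None = None):
    """NRMS curves and band-power curves per group on the normalized axis.

    Returns (grid, nrms_by_group, band_curves_by_group) where band curves are
    dicts band -> (n_traj, n_grid) arrays.
    """
    config = config or AnalysisConfig()
    grid = None
    nrms_by_group: dict[str, list[np.ndarray]] = {}
    band_by_group: dict[str, dict[str, list[np.ndarray]]] = {}
    for tid, tf in features.items():
        ann = annotations.get(tid)
        if ann is None or "degenerate" in ann.flags:
            continue
        grid, nrms_g = normalize_depth_axis(tf.depths_mm, tf.nrms, ann,
                                            n_grid=config.n_grid)
        nrms_by_group.setdefault(tf.group, []).append(nrms_g)
        bands = band_by_group.setdefault(tf.group, {})
        for name in tf.band_powers.columns:
            _, bg = normalize_depth_axis(
                tf.depths_mm, tf.band_powers[name].to_numpy(), ann,
                n_grid=config.n_grid)
            bands.setdefault(name, []).append(bg)
    nrms_arr = {g: np.vstack(v) for g, v in nrms_by_group.items()}
    band_arr = {g: {b: np.vstack(v) for b, v in d.items()}
                for g, d in band_by_group.items()}
    return grid, nrms_arr, band_arr


def compare_stage(summaries: Iterable[TrajectorySummary],
                  patient_metrics: Mapping[str, Mapping[str, object]] | None = None,
                  config: AnalysisConfig | None = None) -> dict[str, GroupComparison]:
    """Group comparisons for the trajectory-level metrics.

    ``patient_metrics`` optionally maps group -> patient -> PatientMetrics to
    add firing-rate / CV-ISI comparisons (IQR outlier removal is applied to
    those, not to the spectral metrics).
    """
    config = config or AnalysisConfig()
    df = pd.DataFrame([{"group": s.group, "beta_ratio": s.beta_ratio,
                        "nrms_peak": s.nrms_peak, "nrms_auc": s.nrms_auc}
                       for s in summaries])
    out: dict[str, GroupComparison] = {}
    for metric in ("beta_ratio", "nrms_peak", "nrms_auc"):
        by_group = {g: sub[metric].dropna().to_numpy()
                    for g, sub in df.groupby("group")}
        by_group = {g: v for g, v in by_group.items() if v.size >= 3}
        if len(by_group) >= 2:
            out[metric] = compare_groups(by_group, alpha=config.alpha)
    if patient_metrics:
        for metric, attr in (("firing_rate", "firing_rate_hz"),
                             ("cv_isi", "cv_isi")):
            by_group = {}
            for g, patients in patient_metrics.items():
                vals = np.asarray([getattr(m, attr) for m in patients.values()],
                                  dtype=float)
                vals = vals[np.isfinite(vals)]
                if vals.size >= 4:
                    vals, _ = remove_outliers_iqr(vals, config.iqr_multiplier)
                if vals.size >= 3:
                    by_group[g] = vals
            if len(by_group) >= 2:
                out[metric] = compare_groups(by_group, alpha=config.alpha)
    return out


def subsample_patients(manifest: pd.DataFrame, n_per_group: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """Manifest rows restricted to ``n_per_group`` patients per group.

    Single-unit metrics are compared across a fixed number of patients per
    group (default 10); the draw is deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    keep = []
    for g, sub in manifest.groupby("group", sort=False):
        patients = sub["patient_id"].unique()
        if patients.size > n_per_group:
            patients = rng.choice(patients, size=n_per_group, replace=False)
        keep.append(sub[sub["patient_id"].isin(patients)])
    return pd.concat(keep, ignore_index=True)


def percent_motor_by_group(grid, band_curves_by_group,
                           config: AnalysisConfig | None = None,
                           ) -> dict[str, tuple[float, bool]]:
    """Percent-motor estimate from the group-averaged band profiles."""
    config = config or AnalysisConfig()
    out = {}
    for g, bands in band_curves_by_group.items():
        beta = bands["beta"].mean(axis=0)
        delta = bands["delta"].mean(axis=0) if "delta" in bands else None
        out[g] = percent_motor(grid, beta, delta,
                               contrast_floor=config.changepoint_contrast_floor,
                               fallback_percent=100 * config.motor_fallback_fraction)
    return out
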