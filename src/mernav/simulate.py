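"""Synthetic microelectrode-recording (MER) trajectories through the STN.

The generator emulates the electrophysiological structure of intraoperative
navigation recordings in Parkinson's disease DBS surgery:

* wideband extracellular noise whose standard deviation rises at STN entry
  (the basis of the normalized-RMS navigation statistic),
* multiunit spiking modeled as a dead-time Poisson process convolved with a
  biphasic extracellular waveform,
* rhythmic modulation of the spiking intensity — beta (default 17 Hz) in the
  motor (dorsolateral) subregion, delta (default 3 Hz) throughout the STN for
  the nitrous-oxide profile, and broadband gamma (31–70 Hz) envelope
  modulation in the non-motor (ventromedial) subregion,
* a low-frequency field component phase-locked to the same modulation, so
  spike-triggered averages of the LFP reproduce the entrainment signatures.

Every trajectory carries its full ground truth (entry/exit/motor-border
indices, true firing rate, profile parameters) for parameter-recovery
testing.  Identical seeds reproduce identical data bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .borders import StnAnnotation

GROUPS = ("awake", "ketamine", "n2o")
REGIONS = ("pre", "motor_stn", "nonmotor_stn", "post")

#: Absolute dead time of the spike generator (s); mimics the neuronal
#: refractory period and guarantees detected trains satisfy the 1.5 ms
#: refractory rule of the analysis side.
DEAD_TIME_S = 0.003


@dataclass(frozen=True)
class AnesthesiaProfile:
    """Group-level signal signature of one anesthetic state.

    ``mean_rate_hz``/``rate_sd_hz`` give the between-trajectory distribution
    of the multiunit firing rate.  ``background_gain_stn`` multiplies the
    background-noise SD inside the STN relative to the pre-STN baseline.
    Modulation depths are fractions of the mean spiking intensity.
    """

    label: str
    mean_rate_hz: float
    rate_sd_hz: float
    background_gain_stn: float
    beta_mod_depth: float
    delta_mod_depth: float
    gamma_level: float
    motor_fraction: float
    beta_freq_hz: float = 17.0
    delta_freq_hz: float = 3.0
    noise_sd_uv: float = 10.0      # baseline background SD, microvolts
    spike_amplitude_sd: float = 8.0  # waveform peak, multiples of noise SD
    lfp_gain_sd: float = 1.0       # LFP amplitude per unit modulation depth
    secondary_unit: bool = False   # optional 3-sigma background unit

    def __post_init__(self) -> None:
        if self.label not in GROUPS:
            raise ValueError(f"unknown group label {self.label!r}")
        if self.mean_rate_hz <= 0:
            raise ValueError("mean_rate_hz must be > 0")
        if self.rate_sd_hz < 0:
            raise ValueError("rate_sd_hz must be >= 0")
        if self.background_gain_stn < 1.0:
            raise ValueError("background_gain_stn must be >= 1")
        for name in ("beta_mod_depth", "delta_mod_depth", "gamma_level", "motor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: Default group profiles. Firing rates and motor fractions follow the study
#: group values (awake 35.95, ketamine 32.08, N2O 24.57 spikes/s; motor
#: 57.9/56.1/64.6 %); background gains and modulation depths encode the
#: qualitative ordering of NRMS and beta attenuation across groups.
AWAKE = AnesthesiaProfile("awake", 35.95, 3.42, 2.5, 0.30, 0.0, 0.3, 0.579)
KETAMINE = AnesthesiaProfile("ketamine", 32.08, 4.79, 2.2, 0.30, 0.0, 0.3, 0.561)
N2O = AnesthesiaProfile("n2o", 24.57, 10.04, 1.8, 0.05, 0.40, 0.3, 0.646)
DEFAULT_PROFILES: dict[str, AnesthesiaProfile] = {
    "awake": AWAKE, "ketamine": KETAMINE, "n2o": N2O,
}


@dataclass(frozen=True)
class TrajectoryPlan:
    """Depth schedule of one trajectory: 0.4 mm steps before the STN, 0.1 mm
    inside and past it, 4 s of analyzed signal per site.

    Depths are "estimated distance to target" (mm) and strictly decrease as
    the electrode advances; the STN entry boundary sits ``entry_depth_mm``
    above the planned target.
    """

    stn_length_mm: float
    pre_length_mm: float = 10.0
    post_length_mm: float = 1.0
    step_pre_mm: float = 0.4
    step_in_mm: float = 0.1
    site_duration_s: float = 4.0
    sampling_rate_hz: float = 44_000.0
    entry_depth_mm: float = 5.0
    depths_mm: np.ndarray = field(init=False, repr=False, compare=False)
    n_pre: int = field(init=False)
    n_stn: int = field(init=False)
    n_post: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("stn_length_mm", "pre_length_mm", "step_pre_mm",
                     "step_in_mm", "site_duration_s", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.post_length_mm < 0:
            raise ValueError("post_length_mm must be >= 0")
        n_pre = math.floor(self.pre_length_mm / self.step_pre_mm + 1e-9) + 1
        n_stn = math.floor(self.stn_length_mm / self.step_in_mm + 1e-9) + 1
        n_post = math.floor(self.post_length_mm / self.step_in_mm + 1e-9)
        entry = self.entry_depth_mm
        pre = entry + self.step_pre_mm * np.arange(n_pre, 0, -1)
        stn = entry - self.step_in_mm * np.arange(n_stn)
        post = stn[-1] - self.step_in_mm * np.arange(1, n_post + 1)
        object.__setattr__(self, "depths_mm", np.concatenate([pre, stn, post]))
        object.__setattr__(self, "n_pre", n_pre)
        object.__setattr__(self, "n_stn", n_stn)
        object.__setattr__(self, "n_post", n_post)

    @property
    def n_sites(self) -> int:
        return self.n_pre + self.n_stn + self.n_post

    @property
    def entry_index(self) -> int:
        return self.n_pre

    @property
    def exit_index(self) -> int:
        return self.n_pre + self.n_stn - 1

    @property
    def exit_depth_mm(self) -> float:
        return float(self.depths_mm[self.exit_index])

    @property
    def samples_per_site(self) -> int:
        return int(round(self.site_duration_s * self.sampling_rate_hz))


def make_trajectory_plan(stn_length_mm: float,
                         pre_length_mm: float = 10.0,
                         post_length_mm: float = 1.0,
                         sampling_rate_hz: float = 44_000.0,
                         **kwargs) -> TrajectoryPlan:
    """Build the explicit depth schedule for one trajectory."""
    return TrajectoryPlan(stn_length_mm=stn_length_mm,
                          pre_length_mm=pre_length_mm,
                          post_length_mm=post_length_mm,
                          sampling_rate_hz=sampling_rate_hz,
                          **kwargs)


@dataclass
class TrajectoryRecording:
    """Ordered per-site wideband signals with depths and ground truth."""

    trajectory_id: str
    patient_id: str
    group: str
    sampling_rate_hz: float
    depths_mm: np.ndarray           # (n_sites,), strictly decreasing
    signals: np.ndarray             # (n_sites, n_samples), microvolts
    ground_truth: StnAnnotation | None = None
    profile: AnesthesiaProfile | None = None
    true_rate_hz: float | None = None
    region_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        if np.any(np.diff(self.depths_mm) >= 0):
            raise ValueError("depths must be strictly decreasing toward target")
        if self.signals.shape[0] != self.depths_mm.size:
            raise ValueError("one signal per depth required")

    @property
    def n_sites(self) -> int:
        return int(self.depths_mm.size)


# ---------------------------------------------------------------------------
# site-level generation
# ---------------------------------------------------------------------------

def deadtime_poisson_train(rate_hz: float, duration_s: float,
                           rng: np.random.Generator,
                           dead_time_s: float = DEAD_TIME_S,
                           modulation: np.ndarray | None = None,
                           fs: float | None = None) -> np.ndarray:
    """Spike times of a dead-time Poisson process with compensated intensity.

    The underlying intensity is lambda = r / (1 - r*d) so the realized rate
    equals the nominal ``rate_hz`` in expectation despite the dead time ``d``.
    ``modulation`` (optional, sampled at ``fs``) multiplies the intensity;
    it should be non-negative with mean ~1.  Modulated processes are drawn by
    thinning a homogeneous proposal at the modulation maximum.
    """
    if rate_hz < 0:
        raise ValueError("rate_hz must be >= 0")
    if rate_hz == 0:
        return np.empty(0)
    if rate_hz * dead_time_s >= 1.0:
        raise ValueError("rate too high for the requested dead time")
    lam0 = rate_hz / (1.0 - rate_hz * dead_time_s)
    if modulation is None:
        mmax = 1.0
    else:
        if fs is None:
            raise ValueError("fs required with modulation")
        mmax = float(max(modulation.max(), 1e-12))
    lam_max = lam0 * mmax
    times = []
    t = rng.exponential(1.0 / lam_max)
    n_mod = 0 if modulation is None else modulation.size
    while t < duration_s:
        if modulation is not None:
            m = modulation[min(int(t * fs), n_mod - 1)]
            if rng.random() * mmax >= m:
                t += rng.exponential(1.0 / lam_max)
                continue
        times.append(t)
        t += dead_time_s + rng.exponential(1.0 / lam_max)
    return np.asarray(times)


def spike_template(fs: float, duration_s: float = 1.5e-3) -> tuple[np.ndarray, int]:
    """Biphasic extracellular waveform (unit peak) and its peak sample index.

    A narrow positive lobe followed by a shallower repolarization trough;
    total duration ~1.5 ms, so its spectral energy sits inside both the
    300–6000 Hz multiunit band and the 300–3000 Hz spike-detection band.
    """
    n = max(int(round(duration_s * fs)), 5)
    t = np.arange(n) / fs
    w = (np.exp(-0.5 * ((t - 4.0e-4) / 1.2e-4) ** 2)
         - 0.45 * np.exp(-0.5 * ((t - 8.5e-4) / 2.5e-4) ** 2))
    w /= w.max()
    return w, int(np.argmax(w))


def _add_waveforms(x: np.ndarray, spike_times: np.ndarray, fs: float,
                   waveform: np.ndarray, peak_index: int) -> None:
    nw = waveform.size
    n = x.size
    for ts in spike_times:
        start = int(round(ts * fs)) - peak_index
        a, b = max(start, 0), min(start + nw, n)
        if a < b:
            x[a:b] += waveform[a - start:b - start]


def _bandlimited_noise(n: int, fs: float, low: float, high: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian noise band-limited to [low, high] Hz."""
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = y.std()
    return y / sd if sd > 0 else y


def simulate_site(plan: TrajectoryPlan, depth_mm: float,
                  profile: AnesthesiaProfile, region_label: str,
                  rng: np.random.Generator,
                  return_spike_times: bool = False):
    """Generate one 4-s site: background noise + spikes + entrained LFP.

    Outside the STN the site is pure Gaussian noise at the baseline SD.
    Inside, the noise SD is multiplied by ``background_gain_stn`` and a
    dead-time Poisson multiunit train (waveform peak ``spike_amplitude_sd``
    times the baseline SD) is added.  The region-dependent rhythmic
    modulation multiplies both the spiking intensity and the background-noise
    envelope — the multiunit hash and the discrete units wax and wane
    together, which is what puts the modulation line into the rectified
    envelope spectrum — and a phase-locked low-frequency field component is
    added so spike-triggered averages expose the same entrainment.
    """
    if region_label not in REGIONS:
        raise ValueError(f"unknown region label {region_label!r}")
    fs = plan.sampling_rate_hz
    n = plan.samples_per_site
    in_stn = region_label in ("motor_stn", "nonmotor_stn")
    sigma0 = profile.noise_sd_uv
    sd = sigma0 * (profile.background_gain_stn if in_stn else 1.0)
    x = rng.normal(0.0, sd, n)
    spike_times = np.empty(0)
    if in_stn and profile.mean_rate_hz > 0:
        t = np.arange(n) / fs
        mod = np.ones(n)
        lfp = np.zeros(n)
        modulated = False
        if region_label == "motor_stn" and profile.beta_mod_depth > 0:
            s = np.sin(2 * np.pi * profile.beta_freq_hz * t + rng.uniform(0, 2 * np.pi))
            mod += profile.beta_mod_depth * s
            lfp += sigma0 * profile.lfp_gain_sd * profile.beta_mod_depth * s
            modulated = True
        if profile.delta_mod_depth > 0:  # applies throughout the STN
            s = np.sin(2 * np.pi * profile.delta_freq_hz * t + rng.uniform(0, 2 * np.pi))
            mod += profile.delta_mod_depth * s
            lfp += sigma0 * profile.lfp_gain_sd * profile.delta_mod_depth * s
            modulated = True
        if region_label == "nonmotor_stn" and profile.gamma_level > 0:
            g = np.clip(_bandlimited_noise(n, fs, 31.0, 70.0, rng), -3.0, 3.0)
            mod += profile.gamma_level * g
            modulated = True
        np.clip(mod, 0.0, None, out=mod)
        if modulated:
            x *= mod  # background envelope follows the same rhythm
        spike_times = deadtime_poisson_train(
            profile.mean_rate_hz, plan.site_duration_s, rng,
            modulation=mod if modulated else None, fs=fs)
        w, peak = spike_template(fs)
        _add_waveforms(x, spike_times, fs,
                       profile.spike_amplitude_sd * sigma0 * w, peak)
        if profile.secondary_unit:
            t2 = deadtime_poisson_train(profile.mean_rate_hz,
                                        plan.site_duration_s, rng)
            _add_waveforms(x, t2, fs, 3.0 * sigma0 * w, peak)
        x += lfp
    if return_spike_times:
        return x, spike_times
    return x


def _region_labels(plan: TrajectoryPlan, motor_fraction: float) -> tuple[list[str], int]:
    """Per-site region labels and the motor-border site index (first
    non-motor STN site)."""
    m = int(round(motor_fraction * (plan.n_stn - 1)))
    m = min(max(m, 1), plan.n_stn - 1)
    labels = (["pre"] * plan.n_pre
              + ["motor_stn"] * m
              + ["nonmotor_stn"] * (plan.n_stn - m)
              + ["post"] * plan.n_post)
    return labels, plan.n_pre + m


def simulate_trajectory(plan: TrajectoryPlan, profile: AnesthesiaProfile,
                        seed: int, trajectory_id: str = "traj",
                        patient_id: str = "patient") -> TrajectoryRecording:
    """Simulate a full trajectory along the plan's depth schedule.

    The trajectory-level firing rate is drawn from the profile's
    between-trajectory distribution (truncated at 1 spike/s); ground-truth
    entry/exit/motor-border indices are embedded in the result.
    """
    rng = np.random.default_rng(seed)
    rate = max(1.0, rng.normal(profile.mean_rate_hz, profile.rate_sd_hz))
    prof_t = replace(profile, mean_rate_hz=rate, rate_sd_hz=0.0)
    labels, motor_border = _region_labels(plan, profile.motor_fraction)
    signals = np.empty((plan.n_sites, plan.samples_per_site))
    for k, (depth, region) in enumerate(zip(plan.depths_mm, labels)):
        signals[k] = simulate_site(plan, depth, prof_t, region, rng)
    annotation = StnAnnotation(
        entry_index=plan.entry_index,
        exit_index=plan.exit_index,
        motor_border_index=motor_border,
        entry_depth_mm=plan.entry_depth_mm,
        exit_depth_mm=plan.exit_depth_mm,
        length_mm=plan.entry_depth_mm - plan.exit_depth_mm,
        method="ground_truth",
    )
    return TrajectoryRecording(
        trajectory_id=trajectory_id, patient_id=patient_id,
        group=profile.label, sampling_rate_hz=plan.sampling_rate_hz,
        depths_mm=plan.depths_mm.copy(), signals=signals,
        ground_truth=annotation, profile=profile, true_rate_hz=rate,
        region_labels=tuple(labels),
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: patients and trajectories per group, STN length
    distribution (uniform on ``stn_length_range``) and master seed."""

    n_patients: Mapping[str, int]
    n_trajectories: Mapping[str, int]
    stn_length_range: tuple[float, float] = (3.0, 8.0)
    pre_length_mm: float = 10.0
    post_length_mm: float = 1.0
    sampling_rate_hz: float = 44_000.0
    site_duration_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stn_length_range
        if not 0 < lo < hi:
            raise ValueError("stn_length_range must satisfy 0 < low < high")
        for counts in (self.n_patients, self.n_trajectories):
            for g, n in dict(counts).items():
                if g not in GROUPS:
                    raise ValueError(f"unknown group {g!r}")
                if n < 1:
                    raise ValueError(f"count for group {g!r} must be >= 1")
        if set(self.n_patients) != set(self.n_trajectories):
            raise ValueError("n_patients and n_trajectories must cover the same groups")
        for g in self.n_trajectories:
            if self.n_trajectories[g] < self.n_patients[g]:
                raise ValueError(f"group {g!r}: more patients than trajectories")

    @classmethod
    def study_default(cls, seed: int = 0, sampling_rate_hz: float = 44_000.0) -> "CohortSpec":
        """The study cohort layout: 35/40/37 patients, 62/67/63 trajectories."""
        return cls(n_patients={"awake": 35, "ketamine": 40, "n2o": 37},
                   n_trajectories={"awake": 62, "ketamine": 67, "n2o": 63},
                   seed=seed, sampling_rate_hz=sampling_rate_hz)


def build_manifest(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic cohort manifest: one row per trajectory.

    Columns: trajectory_id, patient_id, group, seed, stn_length_mm.
    Trajectories are assigned to patients round-robin; per-trajectory seeds
    and STN lengths derive from the master seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.stn_length_range
    rows = []
    for group in spec.n_trajectories:
        n_traj = spec.n_trajectories[group]
        n_pat = spec.n_patients[group]
        for j in range(n_traj):
            rows.append({
                "trajectory_id": f"{group}_t{j:03d}",
                "patient_id": f"{group}_p{j % n_pat:03d}",
                "group": group,
                "seed": int(rng.integers(0, 2**31 - 1)),
                "stn_length_mm": float(rng.uniform(lo, hi)),
            })
    manifest = pd.DataFrame(rows)
    if manifest["trajectory_id"].duplicated().any():
        raise ValueError("duplicate trajectory identifiers in manifest")
    return manifest


def simulate_cohort(spec: CohortSpec,
                    profiles: Mapping[str, AnesthesiaProfile] | None = None,
                    ) -> tuple[pd.DataFrame, Iterator[TrajectoryRecording]]:
    """Manifest plus a lazy stream of simulated trajectories.

    Recordings are generated on demand (a full cohort does not fit in memory
    at once); iterating twice requires calling again, which reproduces the
    identical data for the same spec.
    """
    if profiles is None:
        profiles = DEFAULT_PROFILES
    missing = set(spec.n_trajectories) - set(profiles)
    if missing:
        raise ValueError(f"no profile for groups {sorted(missing)}")
    manifest = build_manifest(spec)

    def _gen() -> Iterator[TrajectoryRecording]:
        for row in manifest.itertuples():
            plan = make_trajectory_plan(
                row.stn_length_mm,
                pre_length_mm=spec.pre_length_mm,
                post_length_mm=spec.post_length_mm,
                sampling_rate_hz=spec.sampling_rate_hz,
                site_duration_s=spec.site_duration_s,
            )
            yield simulate_trajectory(plan, profiles[row.group], row.seed,
                                      trajectory_id=row.trajectory_id,
                                      patient_id=row.patient_id)

    return manifest, _gen()
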