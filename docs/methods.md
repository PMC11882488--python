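# Methods

## Problem setting

During deep brain stimulation (DBS) surgery for Parkinson's disease, the
subthalamic nucleus (STN) is localized by advancing a microelectrode along a
planned trajectory and recording extracellular activity at discrete depth
steps (0.4 mm above the nucleus, 0.1 mm inside it, 4 s of analyzed signal
per site).  Two families of statistics drive navigation:

* **Normalized RMS (NRMS).**  The root mean square of the 300–6000 Hz
  band-passed signal at each site, divided by the mean RMS of the first five
  baseline sites (recorded well above the STN, typically in the internal
  capsule).  Background activity rises sharply at STN entry, so NRMS ≈ 1
  before the nucleus and NRMS > 1 inside it.
* **Envelope spectra.**  The power spectral density of the rectified
  band-passed signal, normalized to total power so each bin is a fraction of
  the site's power.  This "envelope PSD" captures rhythmic modulation of
  multiunit activity: beta-band (13–30 Hz) modulation marks the dorsolateral
  *motor* subregion, broad gamma (31–70 Hz) the ventromedial non-motor
  subregion, and low-frequency (delta, ~3 Hz) modulation appears under
  deep anesthesia.

The package implements these statistics, STN border/subdomain delineation,
the beta-ratio score, single/multi-unit spike metrics with spike-triggered
LFP averaging, and the three-group statistical comparison (awake vs.
low-dose ketamine sedation vs. nitrous-oxide–ketamine general anesthesia),
driven by a synthetic generator with full ground truth.

## Synthetic MER generator

Each site of a trajectory is simulated as

```
x(t) = m(t) · n(t) + a · Σ_k w(t − t_k) + L(t)
```

* `n(t)` — Gaussian background noise with SD σ₀ (default 10 µV) outside the
  STN and σ₀ · `background_gain_stn` inside (defaults 2.5 / 2.2 / 1.8 for
  the awake / ketamine / N2O profiles, encoding the reported ordering of the
  NRMS elevation).
* spike times `t_k` — a dead-time Poisson process with 3 ms absolute dead
  time and intensity λ = r / (1 − r·d), so the realized rate equals the
  nominal rate `r` in expectation.  Group rates default to the reported
  values 35.95 / 32.08 / 24.57 spikes/s with between-trajectory SDs
  3.42 / 4.79 / 10.04.  `w` is a biphasic waveform (~1.5 ms, narrow positive
  lobe, 0.45-relative repolarization trough) with peak amplitude `a` = 8 σ₀.
* `m(t)` — the rhythmic modulation: `1 + m_β sin(2π·17 t + φ)` in the motor
  subregion (depth 0.30 awake/ketamine, 0.05 N2O), `+ m_δ sin(2π·3 t + φ)`
  throughout the STN for the N2O profile (depth 0.40), and a band-limited
  (31–70 Hz) unit-SD Gaussian term scaled by `gamma_level` (0.3) in the
  non-motor subregion.  The same `m(t)` multiplies the spiking intensity
  (via thinning) *and* the background-noise envelope: the multiunit hash and
  the resolvable units wax and wane together, which is what places the
  modulation line in the rectified-envelope spectrum.  Modulating only the
  spike intensity leaves the envelope spectrum dominated by spike shot
  noise, whose band fractions scale inversely with the background gain and
  would invert the group ordering of the beta ratio.
* `L(t)` — a low-frequency field component, phase-locked to the modulation
  terms with amplitude σ₀ · `lfp_gain_sd` · depth, so spike-triggered
  averages expose beta entrainment for awake/ketamine and delta entrainment
  for N2O.  `L` lies entirely below the 300 Hz analysis filters and does not
  perturb RMS or the envelope spectra.

Ground truth (entry/exit/motor-border indices, true rate, profile
parameters) is embedded in every `TrajectoryRecording`.  Identical seeds
reproduce cohorts bit-for-bit; per-trajectory seeds derive from the cohort
master seed.

Deliberate simplifications: background noise is white (real recordings have
colored noise and movement/cautery artifacts); there is one dominant unit
plus an optional low-amplitude secondary unit rather than a sorted
population; the substantia-nigra exit signature, tremor artifacts and the
2 s per-site stabilization period are not simulated.  Passing
parameter-recovery tests therefore demonstrates correctness of the analysis
chain under the stated signal model, not robustness to every property of
operating-room data.

### Geometry

Depths are "estimated distance to target" in mm, strictly decreasing as the
electrode advances.  The STN entry boundary sits 5 mm above target by
default; pre-STN sites are placed at entry + 0.4·k (k = n_pre..1) and STN
sites at entry − 0.1·j (j = 0..n_stn−1) with
n_pre = ⌊pre_length/0.4⌋ + 1 and n_stn = ⌊L/0.1⌋ + 1 (endpoints inclusive),
so a 10 mm pre-segment and a 6 mm STN give 26 + 61 sites and the ground
truth entry−exit depth difference equals L exactly.  A 1 mm post-STN
segment of baseline-level noise exercises exit detection.

## Feature extraction

* Filters are zero-phase (forward–backward) 4th-order Butterworth designs;
  the analysis is offline, so non-causal filtering is the natural choice and
  matches the explicitly non-causal beta filter used for the spike-triggered
  average.  The upper band edge is clipped to 0.45·fs with a warning when
  the sampling rate cannot support it.
* The envelope PSD uses Welch's method with 3 s Hann segments and 50 %
  overlap — the only estimator configuration consistent with a 1/3 Hz
  resolution on a 4 s record.  The envelope mean is removed before the
  spectrum so the DC bin of the rectified signal does not dominate.  Values
  are normalized by total power over the full computed range (up to
  Nyquist); bins up to 200 Hz are reported.  Because the normalization
  range depends on the sampling rate, all scale-sensitive thresholds
  downstream (changepoint contrast) are defined relative to profile means,
  never as absolute fractions.
* NRMS uses the first 5 sites as baseline (configurable; clinical practice
  uses the first 5–6).
* Band powers are sums of PSD bins over delta 1–4, theta-alpha 4–12, beta
  13–30, gamma 31–70 and high 70–150 Hz (low edge inclusive, high edge
  exclusive).
* For group averaging, features are resampled by linear interpolation onto
  a fixed 100-point grid over the normalized depth axis [−0.5, 1], where 0
  is STN entry, 1 is exit, and the pre-entry segment of physical length
  L/2 maps to [−0.5, 0).

## Border detection

The proprietary real-time border algorithm used clinically is replaced by a
declared, simplified scheme:

* **Entry/exit** — entry is the first site starting a run of ≥ 3
  consecutive sites with NRMS ≥ 1.25; exit is the last site of the final
  such run.  The run-length requirement rejects single-site noise spikes;
  both parameters are configurable.  No qualifying run yields a
  "no STN detected" result (None), flagged rather than raised, so cohort
  processing continues.
* **Motor border** — the single changepoint of the beta band-power profile
  over sites in (entry, exit] maximizing |mean_left − mean_right| with at
  least 2 sites per side, ties broken toward the earlier site (conservative
  motor extent).  If the relative contrast (|Δmean| / overall mean) is
  below 0.2 the delta profile is tried; if both are indistinct the border
  falls back to entry + ¼ (exit − entry) and the trajectory is flagged
  `subdomain-indistinct`.  The relative form makes the floor invariant to
  the fs-dependent absolute scale of PSD fractions.  Under the N2O profile
  the beta contrast is weak and delta modulation spans the whole nucleus,
  so those trajectories take the fallback more often than awake ones —
  the intended emulation of the reduced subdomain visibility under nitrous
  oxide.
* **Percent motor** — computed on group-averaged band profiles over the
  normalized axis (not per trajectory), using the same changepoint.
* Expert corrections enter as an override table mapping trajectory to
  indices; corrected annotations are marked `method="corrected"`.

## Spike analysis

Detection on the 300–3000 Hz band-passed signal follows three rules:
candidates are local extrema of |x| at or above 4·σ̂ (both polarities);
a 1.5 ms refractory pass suppresses candidates too close after an accepted
one; a collision pass then removes any surviving spike with another
surviving spike strictly inside (−1 ms, +2 ms) around it, evaluated against
the pre-pass set — for a close pair this removes the earlier spike (the
later one falls in its +2 ms window).  A "remove both" policy is available
behind configuration.  σ̂ is the spike-resistant median-based estimate
median(|x|)/0.6745 by default; the plain SD is available for sensitivity
analysis.  An exhaustive brute-force implementation of the same three rules
serves as the test oracle, with exact agreement required.

Two small biases partially cancel in rate estimation: band-limited Gaussian
noise crosses the 4σ threshold at a small but nonzero Rice rate (false
positives), while the spikes themselves inflate the median-based σ̂ and
thereby raise the threshold.  At the default amplitudes the net effect
stays within the 3-standard-error recovery band used by the validation
suite.

CV-ISI is the sample SD of inter-spike intervals over their mean, undefined
below 3 spikes.  Patient-level aggregation implements both pooling of all
within-site ISIs and averaging of per-site estimates; both are returned.
IQR-based outlier removal (1.5 × IQR fences, linearly interpolated
quartiles) is applied to firing-rate/CV metrics before group testing, not
to spectral metrics.

Spike-triggered averages window the band-passed (1–70 Hz "LFP" or 13–30 Hz
beta), zero-phase-filtered and 1 kHz-decimated signal from 1 s before to
2 s after each spike.  Windows never span site boundaries; spikes whose
window exceeds the record are skipped and counted.  Because a 3 s window on
4 s sites discards most spikes, the STA accumulates across all sites of a
recording stream.

## Group statistics

The beta ratio divides the mean beta fraction over sites in the first
quarter of the STN (the motor definition that remains usable when the
border cannot be trusted per-trajectory; "first half" is supported and
yields the same ordering) by the mean beta fraction over pre-STN sites
within half an STN length above entry.  Fractions of total power are used
rather than absolute band power, consistent with the normalized PSD; the
ratio is therefore invariant to overall amplitude scaling.

NRMS peak and AUC are the maximum and trapezoidal integral of the
grid-resampled NRMS over [0, 1].

`compare_groups` gates on Shapiro–Wilk normality per group at α = 0.05:
one-way ANOVA when every group passes, Kruskal–Wallis otherwise.  When the
omnibus test rejects, pairwise Welch t-tests (robust to unequal variances)
are Bonferroni-corrected by the number of pairs (3 for three groups).
Degenerate inputs (all values identical) raise a dedicated error; constant
groups with distinct means are handled without crashing (a zero-variance
pair with equal means reports p = 1, with distinct means p = 0).

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script run at 20 kHz sampling
(the generator default is 44 kHz, configurable), 4 s sites, with 60 sites
(240 s) per firing-rate recovery, 50 trajectories for border recovery and
20 trajectories per group for the cohort-level discrimination — the scale
at which the standard errors of the recovered quantities are comfortably
inside the acceptance bands.  Type-I error control of the comparison
machinery is checked at the metric level (1000 replicate draws) rather
than by re-simulating signal-level cohorts.

Known limitations: thresholds of the border detector are validated only on
synthetic data (no numeric criterion exists for the clinical "increase in
background noise"); the noise amplitude and spike SNR of real recordings
are conventions, not calibrations; percent-motor under the N2O profile
relies on the group-average profile and may take the flagged fallback when
modulation contrasts are weak.
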