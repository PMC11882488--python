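"""Generator contracts: geometry, determinism, rate compensation, spectral
signatures of the anesthesia profiles."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sstats

from mernav.features import bandpass_spiking, compute_site_psd
from mernav.simulate import (AWAKE, GROUPS, KETAMINE, N2O, CohortSpec,
                             build_manifest, deadtime_poisson_train,
                             make_trajectory_plan, simulate_cohort,
                             simulate_site, simulate_trajectory)

from conftest import FS_TEST


class TestTrajectoryPlan:
    @pytest.mark.parametrize("stn,pre,n_pre,n_stn", [
        (6.0, 10.0, 26, 61),
        (3.0, 10.0, 26, 31),
        (4.0, 4.0, 11, 41),
    ])
    def test_site_counts(self, stn, pre, n_pre, n_stn):
        plan = make_trajectory_plan(stn, pre, 0.0, FS_TEST)
        assert (plan.n_pre, plan.n_stn, plan.n_post) == (n_pre, n_stn, 0)
        assert plan.n_sites == n_pre + n_stn

    @pytest.mark.parametrize("kwargs", [
        {"stn_length_mm": 0.0}, {"stn_length_mm": -1.0},
        {"stn_length_mm": 4.0, "pre_length_mm": 0.0},
        {"stn_length_mm": 4.0, "sampling_rate_hz": 0.0},
    ])
    def test_invalid_arguments(self, kwargs):
        kwargs.setdefault("pre_length_mm", 10.0)
        kwargs.setdefault("sampling_rate_hz", FS_TEST)
        with pytest.raises(ValueError):
            make_trajectory_plan(**kwargs)

    def test_depth_schedule(self):
        plan = make_trajectory_plan(6.0, 10.0, 1.0, FS_TEST)
        d = plan.depths_mm
        assert np.all(np.diff(d) < 0), "depths strictly decrease toward target"
        assert d[plan.entry_index] == pytest.approx(plan.entry_depth_mm)
        # electrophysiological span equals the requested length
        assert d[plan.entry_index] - d[plan.exit_index] == pytest.approx(6.0)
        # step sizes
        assert np.allclose(np.diff(d[:plan.n_pre]), -0.4)
        assert np.allclose(np.diff(d[plan.n_pre:plan.exit_index + 1]), -0.1)


class TestSiteGeneration:
    def test_pre_region_is_pure_noise(self):
        plan = make_trajectory_plan(4.0, 4.0, 0.0, FS_TEST)
        rng = np.random.default_rng(0)
        sig = simulate_site(plan, 6.0, AWAKE, "pre", rng)
        assert sig.size == plan.samples_per_site
        rms = np.sqrt(np.mean(sig ** 2))
        assert rms == pytest.approx(AWAKE.noise_sd_uv, rel=0.02)

    def test_unknown_region_rejected(self):
        plan = make_trajectory_plan(4.0, 4.0, 0.0, FS_TEST)
        with pytest.raises(ValueError, match="region"):
            simulate_site(plan, 6.0, AWAKE, "thalamus", np.random.default_rng(0))

    def test_stn_background_gain(self):
        plan = make_trajectory_plan(4.0, 4.0, 0.0, FS_TEST)
        prof = dataclasses.replace(AWAKE, beta_mod_depth=0.0, gamma_level=0.0,
                                   mean_rate_hz=1e-9)
        rng = np.random.default_rng(1)
        sig = simulate_site(plan, 3.0, prof, "nonmotor_stn", rng)
        rms = np.sqrt(np.mean(sig ** 2))
        assert rms == pytest.approx(
            AWAKE.noise_sd_uv * AWAKE.background_gain_stn, rel=0.02)

    def test_deadtime_poisson_rate_compensation(self):
        """Realized rate matches nominal within 3 SE over 240 s despite the
        3 ms dead time."""
        rng = np.random.default_rng(7)
        for rate in (10.0, 25.0, 36.0):
            times = deadtime_poisson_train(rate, 240.0, rng)
            realized = times.size / 240.0
            se = np.sqrt(rate / 240.0)
            assert abs(realized - rate) < 3 * se
            assert np.diff(times).min() >= 0.003

    def test_beta_envelope_peak_present_when_modulated(self):
        """The 17 Hz envelope line appears with modulation and not without.

        Rank comparison of the modulation-bin fraction across replicate
        sites against a modulation-free control (Mann-Whitney); a
        control-vs-control contrast serves as the null check.
        """
        plan = make_trajectory_plan(4.0, 4.0, 0.0, FS_TEST)
        fs = plan.sampling_rate_hz

        def line_bins(profile, n_rep=15, seed=11):
            rng = np.random.default_rng(seed)
            out = []
            for _ in range(n_rep):
                sig = simulate_site(plan, 4.0, profile, "motor_stn", rng)
                f, p = compute_site_psd(bandpass_spiking(sig, fs), fs)
                out.append(p[np.argmin(np.abs(f - profile.beta_freq_hz))])
            return np.asarray(out)

        modulated = dataclasses.replace(AWAKE, rate_sd_hz=0.0)
        control = dataclasses.replace(AWAKE, beta_mod_depth=0.0,
                                      rate_sd_hz=0.0)
        assert sstats.mannwhitneyu(line_bins(modulated), line_bins(control),
                                   alternative="greater").pvalue < 0.05
        assert sstats.mannwhitneyu(line_bins(control, seed=12),
                                   line_bins(control, seed=13),
                                   alternative="greater").pvalue > 0.05

    def test_n2o_delta_peak_beta_absent(self):
        plan = make_trajectory_plan(4.0, 4.0, 0.0, FS_TEST)
        fs = plan.sampling_rate_hz
        rng = np.random.default_rng(3)
        prof = dataclasses.replace(N2O, rate_sd_hz=0.0)
        acc = None
        for _ in range(10):
            sig = simulate_site(plan, 4.0, prof, "motor_stn", rng)
            f, p = compute_site_psd(bandpass_spiking(sig, fs), fs)
            acc = p if acc is None else acc + p
        acc /= 10
        low = f >= 1.0
        peak_freq = f[low][np.argmax(acc[low])]
        assert abs(peak_freq - prof.delta_freq_hz) <= 1.0 / 3.0 + 1e-9
        # delta line dwarfs anything in the beta band
        beta = (f >= 13) & (f < 30)
        assert acc[low].max() > 10 * acc[beta].max()


class TestTrajectoryAndCohort:
    def test_site_count_and_duration(self):
        plan = make_trajectory_plan(6.0, 10.0, 0.0, FS_TEST)
        rec = simulate_trajectory(plan, KETAMINE, seed=5)
        assert rec.n_sites == 87
        assert rec.signals.shape[1] == int(4.0 * FS_TEST)

    def test_determinism_same_seed(self):
        plan = make_trajectory_plan(3.0, 4.0, 0.0, FS_TEST)
        a = simulate_trajectory(plan, AWAKE, seed=9)
        b = simulate_trajectory(plan, AWAKE, seed=9)
        assert np.array_equal(a.signals, b.signals)
        assert a.true_rate_hz == b.true_rate_hz
        c = simulate_trajectory(plan, AWAKE, seed=10)
        assert not np.array_equal(a.signals, c.signals)

    def test_ground_truth_geometry(self):
        plan = make_trajectory_plan(5.0, 6.0, 1.0, FS_TEST)
        rec = simulate_trajectory(plan, N2O, seed=2)
        gt = rec.ground_truth
        assert gt.entry_index < gt.motor_border_index <= gt.exit_index
        assert gt.entry_depth_mm - gt.exit_depth_mm == pytest.approx(5.0, abs=0.1)
        assert rec.region_labels[gt.entry_index] == "motor_stn"
        assert rec.region_labels[gt.entry_index - 1] == "pre"
        assert rec.region_labels[gt.exit_index] == "nonmotor_stn"

    def test_study_manifest_has_192_rows(self):
        manifest = build_manifest(CohortSpec.study_default(seed=0))
        assert len(manifest) == 192
        assert manifest["group"].value_counts().to_dict() == {
            "ketamine": 67, "n2o": 63, "awake": 62}

    def test_minimal_manifest(self):
        spec = CohortSpec(n_patients={g: 1 for g in GROUPS},
                          n_trajectories={g: 1 for g in GROUPS})
        assert len(build_manifest(spec)) == 3

    def test_cohort_determinism(self):
        spec = CohortSpec(n_patients={"awake": 1}, n_trajectories={"awake": 1},
                          stn_length_range=(3.0, 3.5),
                          pre_length_mm=3.0, post_length_mm=0.0,
                          sampling_rate_hz=FS_TEST, seed=77)
        m1, g1 = simulate_cohort(spec)
        m2, g2 = simulate_cohort(spec)
        assert m1.equals(m2)
        r1, r2 = next(g1), next(g2)
        assert np.array_equal(r1.signals, r2.signals)

    def test_cohort_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients={"awake": 0}, n_trajectories={"awake": 1})
        with pytest.raises(ValueError):
            CohortSpec(n_patients={"awake": 1}, n_trajectories={"awake": 1},
                       stn_length_range=(8.0, 3.0))
        with pytest.raises(ValueError):
            CohortSpec(n_patients={"cortex": 1}, n_trajectories={"cortex": 1})

    def test_realized_firing_rate_matches_nominal(self):
        """Ground-truth spike counts over 240 s sit within 3 SE of nominal."""
        plan = make_trajectory_plan(4.0, 4.0, 0.0, FS_TEST)
        prof = dataclasses.replace(AWAKE, rate_sd_hz=0.0, beta_mod_depth=0.0,
                                   gamma_level=0.0)
        rng = np.random.default_rng(21)
        count = 0
        for _ in range(60):
            _, st = simulate_site(plan, 4.0, prof, "motor_stn", rng,
                                  return_spike_times=True)
            count += st.size
        rate = count / 240.0
        assert abs(rate - prof.mean_rate_hz) < 3 * np.sqrt(prof.mean_rate_hz / 240.0)


def test_subsample_patients_limits_group_size():
    """Single-unit comparisons draw a fixed number of patients per group."""
    from mernav.pipeline import subsample_patients
    manifest = build_manifest(CohortSpec.study_default(seed=0))
    sub = subsample_patients(manifest, n_per_group=10, seed=1)
    counts = sub.groupby("group")["patient_id"].nunique()
    assert (counts == 10).all()
    assert sub.equals(subsample_patients(manifest, n_per_group=10, seed=1))
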