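import numpy as np
import pytest

from axoprop.analysis import (
    align_average,
    delay_distance_profile,
    detect_ap_and_align,
    epsp_metrics,
    extract_inap_gv,
    fi_curve,
    fit_boltzmann,
    fit_gain,
    fit_propagation_velocities,
    integral_peak_slope,
    passive_properties,
)
from axoprop.synth import (
    GeneratorSpec,
    gen_action_current_set,
    gen_epsp_set,
    gen_fi_trains,
    gen_passive_step,
    gen_ramp_inap,
)
from axoprop.traces import Channel


class TestEventDetection:
    def test_sigmoid_spike_dvdt_max_at_inflection(self):
        t = np.arange(0.0, 20.0, 0.01)
        v = -75.0 + 110.0 / (1.0 + np.exp(-(t - 10.0) / 0.2))
        ev = detect_ap_and_align(v, t)
        assert ev[0] == pytest.approx(10.0, abs=0.01)

    def test_offset_invariance(self):
        t = np.arange(0.0, 20.0, 0.01)
        v = -75.0 + 110.0 / (1.0 + np.exp(-(t - 10.0) / 0.2))
        assert detect_ap_and_align(v, t) == pytest.approx(
            detect_ap_and_align(v + 13.0, t), abs=1e-9)

    def test_flat_trace_gives_empty_result(self):
        t = np.arange(0.0, 20.0, 0.01)
        assert detect_ap_and_align(np.full_like(t, -75.0), t) == []

    def test_action_current_timed_at_inward_peak(self):
        ts = gen_action_current_set(seed=3)
        truth = ts.meta["truth"]
        ch = [c for c in ts.channels if c.quantity == "I_membrane"][0]
        ev = detect_ap_and_align(ch, ts.time)
        expected = truth["t_ref_ms"] + truth["delays_ms"][ch.distance]
        assert ev[0] == pytest.approx(expected, abs=2e-3)

    def test_jittered_sweep_alignment_recovers_jitter(self):
        spec = GeneratorSpec("action_current_set", seed=11, jitter_sigma=0.05,
                             n_sweeps=100)
        ts = gen_action_current_set(spec, sites=(20.0,), width=0.1)
        sweeps = [c for c in ts.channels if c.quantity == "I_membrane"]
        events = [detect_ap_and_align(c, ts.time)[0] for c in sweeps]
        # alignment-and-average sharpens the mean waveform
        rel, avg = align_average([c.samples for c in sweeps], ts.time, events)
        raw_mean = np.mean([c.samples for c in sweeps], axis=0)
        assert np.abs(avg).max() > np.abs(raw_mean).max()
        # per-sweep event recovery to better than one sample (5 us)
        truth = ts.meta["truth"]
        base = truth["t_ref_ms"] + truth["delays_ms"][20.0]
        recovered_jitter = np.std(np.array(events) - base)
        assert abs(recovered_jitter - 0.05) < 0.01


class TestDelayDistanceProfile:
    def test_programmed_delays_recovered_exactly(self):
        ts = gen_action_current_set(seed=0)
        prof = delay_distance_profile(ts, t_from=0.0)
        truth = ts.meta["truth"]["delays_ms"]
        for dist, delay in prof:
            assert delay == pytest.approx(truth[dist], abs=2e-3)

    def test_near_soma_site_has_near_zero_delay(self):
        ts = gen_action_current_set(seed=0, sites=(0.5, 10.0, 30.0, 50.0, 70.0))
        prof = delay_distance_profile(ts, t_from=0.0)
        assert abs(prof[0, 1]) < 0.01

    def test_missing_distance_metadata_rejected(self):
        ts = gen_action_current_set(seed=0)
        for ch in ts.channels:
            if ch.quantity == "I_membrane":
                ch.distance = float("nan")
        with pytest.raises(ValueError, match="distance"):
            delay_distance_profile(ts, t_from=0.0)


class TestVelocityFit:
    def test_noise_free_recovery_within_one_percent(self):
        ts = gen_action_current_set(seed=0)  # 0.32 / 0.10 m/s preset
        est = fit_propagation_velocities(delay_distance_profile(ts, t_from=0.0))
        assert est.forward_m_per_s == pytest.approx(0.32, rel=0.01)
        assert est.backward_m_per_s == pytest.approx(0.10, rel=0.01)
        assert est.ratio == pytest.approx(0.10 / 0.32, rel=0.02)
        assert abs(est.initiation_um - 30.0) <= 4.0

    def test_symmetric_profile_gives_unit_ratio(self):
        x = np.linspace(0, 60, 16)
        delay = np.abs(x - 30.0) / 100.0
        est = fit_propagation_velocities(np.column_stack([x, delay]))
        assert est.ratio == pytest.approx(1.0, rel=1e-9)

    def test_scale_equivariance(self):
        ts = gen_action_current_set(seed=0)
        prof = delay_distance_profile(ts, t_from=0.0)
        est1 = fit_propagation_velocities(prof)
        est2 = fit_propagation_velocities(prof * 2.0)
        assert est2.backward_m_per_s == pytest.approx(est1.backward_m_per_s)
        assert est2.forward_m_per_s == pytest.approx(est1.forward_m_per_s)

    def test_jitter_monte_carlo_median_bias_under_five_percent(self):
        sites = tuple(np.linspace(2.0, 92.0, 20))
        vb, vf = [], []
        for rep in range(200):
            spec = GeneratorSpec("action_current_set", seed=1000 + rep,
                                 jitter_sigma=0.01)  # 10 us
            ts = gen_action_current_set(spec, sites=sites)
            est = fit_propagation_velocities(
                delay_distance_profile(ts, t_from=0.0))
            vb.append(est.backward_m_per_s)
            vf.append(est.forward_m_per_s)
        assert abs(np.median(vb) - 0.10) / 0.10 < 0.05
        assert abs(np.median(vf) - 0.32) / 0.32 < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_propagation_velocities(np.array([[0.0, 0.0], [1.0, 0.1]]))


class TestInapGV:
    def test_leak_only_residual_near_zero(self):
        ts = gen_ramp_inap(seed=0, gmax=0.0)
        gv = extract_inap_gv(ts, normalize=False)
        # residual conductance (uS) negligible vs the 2 nS leak
        assert np.max(np.abs(gv[:, 1])) < 1e-6

    def test_boltzmann_plus_leak_recovered_within_one_percent_rms(self):
        ts = gen_ramp_inap(seed=0)  # V1/2 -50, k 5
        gv = extract_inap_gv(ts)
        truth = 1.0 / (1.0 + np.exp(-(gv[:, 0] + 50.0) / 5.0))
        rms = np.sqrt(np.mean((gv[:, 1] - truth) ** 2))
        assert rms < 0.01

    def test_ais_curve_left_of_somatic_curve(self):
        soma = gen_ramp_inap(seed=0, vhalf=-48.0)
        ais = gen_ramp_inap(seed=0, vhalf=-55.0)  # 7 mV more negative
        f_soma = fit_boltzmann(extract_inap_gv(soma))
        f_ais = fit_boltzmann(extract_inap_gv(ais))
        assert f_ais.vhalf < f_soma.vhalf
        assert f_soma.vhalf - f_ais.vhalf == pytest.approx(7.0, abs=0.3)

    def test_nonmonotonic_command_rejected(self):
        ts = gen_ramp_inap(seed=0)
        ts["Vcmd"].samples[10] = 100.0
        with pytest.raises(ValueError):
            extract_inap_gv(ts)


class TestBoltzmannFit:
    def test_exact_samples_recovered(self):
        v = np.linspace(-80.0, -20.0, 61)
        g = 1.0 / (1.0 + np.exp(-(v + 50.0) / 5.0))
        fit = fit_boltzmann(np.column_stack([v, g]))
        assert fit.vhalf == pytest.approx(-50.0, abs=1e-6)
        assert fit.k == pytest.approx(5.0, abs=1e-6)
        assert not fit.extrapolated

    def test_paired_shift_recovered(self):
        ts = gen_ramp_inap(seed=0, dv_shift=-6.0)
        f0 = fit_boltzmann(extract_inap_gv(ts))
        f6 = fit_boltzmann(extract_inap_gv(ts, current_channel="I_clamp_shifted"))
        assert f6.vhalf - f0.vhalf == pytest.approx(-6.0, abs=0.2)

    def test_noisy_vhalf_rmse_under_half_millivolt(self):
        errs = []
        for rep in range(50):
            spec = GeneratorSpec("ramp_inap", seed=2000 + rep, noise_sigma=0.02)
            fit = fit_boltzmann(extract_inap_gv(gen_ramp_inap(spec)))
            errs.append(fit.vhalf + 50.0)
        assert np.sqrt(np.mean(np.square(errs))) < 0.5

    def test_translation_equivariance(self):
        v = np.linspace(-80.0, -20.0, 61)
        g = 1.0 / (1.0 + np.exp(-(v + 50.0) / 5.0))
        f0 = fit_boltzmann(np.column_stack([v, g]))
        f1 = fit_boltzmann(np.column_stack([v + 7.0, g]))
        assert f1.vhalf - f0.vhalf == pytest.approx(7.0, abs=1e-6)
        assert f1.k == pytest.approx(f0.k, abs=1e-6)

    def test_non_spanning_curve_flagged(self):
        v = np.linspace(-49.0, -40.0, 20)
        g = 1.0 / (1.0 + np.exp(-(v + 50.0) / 5.0))
        fit = fit_boltzmann(np.column_stack([v, g]))
        assert fit.extrapolated


class TestGain:
    def test_programmed_linear_law_recovered_exactly(self):
        ts = gen_fi_trains(seed=0)  # f = 64 I
        gain = fit_gain(fi_curve(ts))
        assert gain.slope_hz_per_na == pytest.approx(64.0, rel=1e-3)

    def test_constant_frequency_gives_zero_slope(self):
        pts = [(0.1, 30.0, 5), (0.2, 30.0, 5), (0.3, 30.0, 5)]
        assert fit_gain(pts).slope_hz_per_na == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_subthreshold_steps(self):
        ts = gen_fi_trains(seed=0)
        pts = fi_curve(ts)
        supra_only = [p for p in pts if p[2] >= 2]
        assert fit_gain(pts).slope_hz_per_na == pytest.approx(
            fit_gain(supra_only).slope_hz_per_na)

    def test_rheobase_bookkeeping(self):
        ts = gen_fi_trains(seed=0)
        gain = fit_gain(fi_curve(ts))
        assert 0.0 < gain.rheobase_na <= 0.1

    def test_irregular_isis_recovered_within_ci(self):
        slopes = []
        for rep in range(30):
            spec = GeneratorSpec("fi_trains", seed=3000 + rep)
            ts = gen_fi_trains(spec, isi_cv=0.1)
            slopes.append(fit_gain(fi_curve(ts)).slope_hz_per_na)
        mean, sem = np.mean(slopes), np.std(slopes) / np.sqrt(len(slopes))
        assert abs(mean - 64.0) < max(3.0 * sem, 1.5)


class TestPassive:
    def test_ideal_rc_recovered_exactly(self):
        ts = gen_passive_step(seed=0)  # 100 MOhm, 20 ms
        fit = passive_properties(ts)
        assert fit.r_in_mohm == pytest.approx(100.0, rel=1e-3)
        assert fit.tau_m_ms == pytest.approx(20.0, rel=1e-3)
        assert not fit.spike_contaminated

    def test_noisy_rc_within_tolerance(self):
        r_errs, tau_errs = [], []
        for rep in range(100):
            spec = GeneratorSpec("passive_step", seed=4000 + rep,
                                 noise_sigma=0.2)
            fit = passive_properties(gen_passive_step(spec))
            r_errs.append(fit.r_in_mohm / 100.0 - 1.0)
            tau_errs.append(fit.tau_m_ms / 20.0 - 1.0)
        assert abs(np.mean(r_errs)) < 0.02
        assert abs(np.mean(tau_errs)) < 0.05


class TestEpsp:
    def test_alpha_integral_is_e_a_tau(self):
        ts = gen_epsp_set(seed=0, peaks=(5.0,), tau0=10.0)
        m = epsp_metrics(ts.time, ts.channels[0].samples, stim_time=10.0)
        assert m.peak_mv == pytest.approx(5.0, rel=1e-3)
        assert m.integral_mv_ms == pytest.approx(5.0 * np.e * 10.0, rel=5e-3)

    def test_constant_tau_family_slope_e_tau(self):
        ts = gen_epsp_set(seed=0)
        ms = [epsp_metrics(ts.time, ch.samples, stim_time=10.0)
              for ch in ts.channels]
        slope = integral_peak_slope(ms)
        assert slope == pytest.approx(np.e * 10.0, rel=0.01)

    def test_peak_dependent_broadening_steepens_slope(self):
        flat = gen_epsp_set(seed=0)
        grow = gen_epsp_set(seed=0, tau_slope=0.8, tau_break=10.0)
        s_flat = integral_peak_slope(
            [epsp_metrics(flat.time, c.samples, stim_time=10.0)
             for c in flat.channels])
        s_grow = integral_peak_slope(
            [epsp_metrics(grow.time, c.samples, stim_time=10.0)
             for c in grow.channels])
        assert s_grow > s_flat * 1.1

    def test_subnoise_peak_excluded(self):
        t = np.arange(0.0, 50.0, 0.1)
        v = np.full_like(t, -75.0)
        assert epsp_metrics(t, v, stim_time=10.0, noise_floor=0.2) is None
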