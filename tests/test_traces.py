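"""Sweep handling, subtraction pipeline, decay fits, passive properties."""

import numpy as np
import pytest

import autapse as ap
from autapse.traces import (
    DifferenceTrace,
    MeanTrace,
    TraceError,
    average_condition,
    bundle_checksum,
    conductance_from_difference,
    detect_escape_spike,
    fit_monoexp_decay,
)


def _sweep(samples, dt=0.02, kind="current_pA", holding=-43.0, cond="control",
           idx=0):
    return ap.Sweep(samples=np.asarray(samples, float), dt_ms=dt,
                    signal_kind=kind, holding_mV=holding, condition=cond,
                    index=idx)


def _sweep_set(sweeps):
    return ap.SweepSet(sweeps=tuple(sweeps), cell_id="c0")


class TestAverageCondition:
    def test_identical_sweeps_average_to_themselves(self):
        base = np.sin(np.linspace(0, 3, 200))
        sset = _sweep_set([_sweep(base, idx=i) for i in range(6)])
        mean = average_condition(sset, "control")
        np.testing.assert_allclose(mean.samples, base)
        assert mean.n_averaged == 6

    def test_fewer_than_minimum_refused(self):
        sset = _sweep_set([_sweep(np.zeros(50), idx=i) for i in range(5)])
        with pytest.raises(TraceError, match="at least 6"):
            average_condition(sset, "control")

    def test_force_overrides_minimum_with_warning(self):
        sset = _sweep_set([_sweep(np.zeros(50), idx=i) for i in range(5)])
        with pytest.warns(UserWarning):
            mean = average_condition(sset, "control", force=True)
        assert mean.n_averaged == 5

    def test_noise_averages_toward_signal(self, rng):
        # mean of 12 noisy copies stays within 3σ/√12 of the signal pointwise
        signal = 10.0 * np.exp(-np.arange(500) * 0.02 / 4.0)
        sigma = 5.0
        sweeps = [
            _sweep(signal + rng.normal(0, sigma, signal.size), idx=i)
            for i in range(12)
        ]
        mean = average_condition(_sweep_set(sweeps), "control", min_count=12)
        assert np.max(np.abs(mean.samples - signal)) < 3 * sigma / np.sqrt(12) * 1.5

    def test_mismatched_lengths_rejected(self):
        sweeps = [_sweep(np.zeros(50), idx=i) for i in range(5)]
        sweeps.append(_sweep(np.zeros(60), idx=5))
        with pytest.raises(TraceError, match="unequal length"):
            average_condition(_sweep_set(sweeps), "control")


class TestActionCurrentZero:
    def test_single_inward_spike_located(self):
        dt = 0.02
        samples = np.zeros(1000)
        samples[int(12.40 / dt)] = -2000.0
        assert ap.action_current_zero(samples, dt_ms=dt) == pytest.approx(12.40)

    def test_tie_breaks_to_earliest(self):
        samples = np.zeros(100)
        samples[[30, 60]] = -500.0
        assert ap.action_current_zero(samples, dt_ms=0.1) == pytest.approx(3.0)

    def test_flat_trace_rejected(self):
        with pytest.raises(TraceError, match="no inward transient"):
            ap.action_current_zero(np.zeros(100), dt_ms=0.1)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(TraceError):
            ap.action_current_zero(np.zeros(100), dt_ms=0.1,
                                   window_ms=(50.0, 60.0))


class TestIsolateBlockerSensitive:
    def _mean(self, samples, n=6):
        return MeanTrace(samples=np.asarray(samples, float), dt_ms=0.02,
                         n_averaged=n, holding_mV=-43.0)

    def test_identical_conditions_give_zero(self):
        base = np.random.default_rng(0).normal(size=300)
        diff = ap.isolate_blocker_sensitive(self._mean(base), self._mean(base),
                                            t0_ms=1.0)
        np.testing.assert_array_equal(diff.samples, 0.0)
        assert diff.n_control == 6 and diff.n_blocker == 6

    def test_linearity_recovers_injected_waveform(self):
        base = np.linspace(0, 1, 300)
        w = np.exp(-np.linspace(0, 6, 300))
        diff = ap.isolate_blocker_sensitive(self._mean(base + w),
                                            self._mean(base), t0_ms=0.0)
        np.testing.assert_allclose(diff.samples, w, atol=1e-12)

    def test_off_event_rms_adds_in_quadrature(self, rng):
        # independent noise σ in each average → difference RMS ≈ σ·√2
        sigma, n = 4.0, 4000
        a = self._mean(rng.normal(0, sigma, n), n=1)
        b = self._mean(rng.normal(0, sigma, n), n=1)
        diff = ap.isolate_blocker_sensitive(a, b, t0_ms=0.0)
        rms = float(np.sqrt(np.mean(diff.samples**2)))
        assert rms == pytest.approx(sigma * np.sqrt(2), rel=0.15)

    def test_mismatched_sampling_rejected(self):
        a = self._mean(np.zeros(100))
        b = MeanTrace(samples=np.zeros(100), dt_ms=0.05, n_averaged=6)
        with pytest.raises(TraceError):
            ap.isolate_blocker_sensitive(a, b, t0_ms=0.0)


class TestPeakAndDelay:
    def _diff_with_peak(self, delay_ms, dt=0.02, t0=8.0):
        t = np.arange(0, 30, dt)
        rel = t - t0 - delay_ms
        samples = 100.0 * np.exp(-(rel / 1.5) ** 2)
        return DifferenceTrace(samples, dt, t0, 6, 6)

    @pytest.mark.parametrize("delay", [2.31, 0.78])
    def test_constructed_delay_recovered(self, delay):
        diff = self._diff_with_peak(delay)
        amp, found = ap.peak_and_delay(diff, "outward", (0.0, 15.0))
        assert found == pytest.approx(delay, abs=0.03)
        assert amp == pytest.approx(100.0, rel=1e-3)

    def test_strictly_decaying_peaks_at_window_start(self):
        t = np.arange(0, 30, 0.02)
        samples = 50.0 * np.exp(-t / 5.0)
        diff = DifferenceTrace(samples, 0.02, 2.0, 6, 6)
        _, delay = ap.peak_and_delay(diff, "outward", (1.0, 10.0))
        assert delay == pytest.approx(1.0, abs=0.06)

    def test_window_before_t0_rejected(self):
        diff = self._diff_with_peak(2.0)
        with pytest.raises(TraceError):
            ap.peak_and_delay(diff, "outward", (-1.0, 10.0))


class TestMonoexpFit:
    def test_exact_exponential_recovered(self):
        dt = 0.02
        t = np.arange(0, 40, dt)
        y = 17.48 * np.exp(-t / 5.43)
        fit = fit_monoexp_decay(y, dt, peak_time_ms=0.0)
        assert fit.tau_ms == pytest.approx(5.43, rel=1e-3)
        assert fit.amplitude_at_peak == pytest.approx(17.48, rel=1e-3)
        assert fit.r2 > 0.999
        assert fit.accepted

    def test_five_percent_noise_within_ten_percent(self, rng):
        dt = 0.02
        t = np.arange(0, 40, dt)
        y = 17.48 * np.exp(-t / 5.43) + rng.normal(0, 0.05 * 17.48, t.size)
        fit = fit_monoexp_decay(y, dt, peak_time_ms=0.0)
        assert fit.tau_ms == pytest.approx(5.43, rel=0.10)

    def test_biexponential_fits_worse_and_flagging_works(self):
        # equal-weight biexponential (τ 1 and 20 ms): the best single
        # exponential leaves structured residuals (r² ≈ 0.94, computed by
        # direct least squares); a stricter threshold flags it
        dt = 0.02
        t = np.arange(0, 60, dt)
        y = 0.5 * np.exp(-t / 1.0) + 0.5 * np.exp(-t / 20.0)
        fit = fit_monoexp_decay(y, dt, peak_time_ms=0.0)
        assert fit.r2 == pytest.approx(0.943, abs=0.01)
        strict = fit_monoexp_decay(y, dt, peak_time_ms=0.0, r2_threshold=0.95)
        assert "low_r2" in strict.flags
        assert strict.tau_ms > 0  # flagged, not discarded

    def test_too_few_samples_rejected(self):
        with pytest.raises(TraceError):
            fit_monoexp_decay(np.ones(8), 0.02, peak_time_ms=0.0,
                              window_end_ms=0.1)


class TestConductanceFromDifference:
    def test_round_trip_peak(self):
        dt, t0 = 0.02, 5.0
        t = np.arange(0, 30, dt)
        w = np.clip(1 - np.abs(t - t0 - 2.0), 0, None)  # unit-peak triangle
        g_true, vh, e = 4.2, -43.0, -73.0
        diff = DifferenceTrace(g_true * (vh - e) * w, dt, t0, 6, 6)
        iso = conductance_from_difference(diff, vh, e)
        assert iso.peak_nS == pytest.approx(g_true, rel=1e-6)

    def test_median_current_gives_printed_conductance(self):
        # smooth rise to the printed 150.2 pA peak, then monoexp decay
        dt, t0 = 0.02, 2.0
        t = np.arange(0, 30, dt)
        rel = t - t0
        samples = np.where(
            rel >= 2.0,
            150.2 * np.exp(-(rel - 2.0) / 4.0),
            np.where(rel > 0, 150.2 * np.sin(0.25 * np.pi * rel) ** 2, 0.0),
        )
        diff = DifferenceTrace(samples, dt, t0, 6, 6)
        iso = conductance_from_difference(diff, -43.0, -73.0)
        assert iso.peak_nS == pytest.approx(5.007, abs=0.01)

    def test_zero_driving_force_rejected(self):
        diff = DifferenceTrace(np.ones(100), 0.02, 0.0, 6, 6)
        with pytest.raises(TraceError):
            conductance_from_difference(diff, -73.0, -73.0)


class TestPassiveFromSteps:
    def test_noiseless_rc_recovered_exactly(self):
        truth = ap.default_ground_truth(noise_sd_mV=0.0)
        steps = ap.generate_step_family(truth)
        props = ap.passive_from_steps(
            steps, (-50.0, 50.0, 100.0), step_start_ms=100.0, step_end_ms=700.0
        )
        assert props.r_m_MOhm == pytest.approx(183.83, rel=1e-3)
        assert props.c_m_pF == pytest.approx(43.81, rel=5e-3)
        assert props.tau_m_ms == pytest.approx(8.0536, rel=5e-3)
        assert props.e_m_mV == pytest.approx(-74.15, abs=0.01)
        assert props.g_leak_nS == pytest.approx(1000.0 / 183.83, rel=1e-3)
        assert not props.flags

    def test_steady_state_deflection_matches_ohms_law(self):
        truth = ap.default_ground_truth(noise_sd_mV=0.0)
        steps = ap.generate_step_family(truth, injected_pA=(-50.0,))
        sweep = steps.sweeps[0]
        i0 = int(round(650.0 / sweep.dt_ms))
        i1 = int(round(700.0 / sweep.dt_ms))
        deflection = sweep.samples[i0:i1].mean() - truth.passive.e_m_mV
        assert deflection == pytest.approx(-9.1915, abs=0.01)

    def test_zero_amplitude_step_rejected(self):
        truth = ap.default_ground_truth(noise_sd_mV=0.0)
        steps = ap.generate_step_family(truth, injected_pA=(-50.0,))
        with pytest.raises(TraceError):
            ap.passive_from_steps(steps, (0.0,), 100.0, 700.0)

    def test_short_step_flagged(self):
        truth = ap.default_ground_truth(noise_sd_mV=0.0)
        steps = ap.generate_step_family(
            truth, injected_pA=(-50.0,), step_duration_ms=20.0, dt_ms=0.05
        )
        props = ap.passive_from_steps(steps, (-50.0,), 100.0, 120.0)
        assert "steady_state_not_reached" in props.flags


class TestShuntRatio:
    def test_zero_autapse_is_unity(self):
        assert ap.shunt_ratio(0.0, 5.44) == 1.0

    def test_equal_conductances_double(self):
        assert ap.shunt_ratio(5.44, 5.44) == 2.0

    def test_median_human_values(self):
        g_leak = 1000.0 / 183.83
        assert ap.shunt_ratio(3.79, g_leak) == pytest.approx(1.697, abs=0.001)

    def test_nonpositive_leak_rejected(self):
        with pytest.raises(TraceError):
            ap.shunt_ratio(1.0, 0.0)


class TestEscapeSpikes:
    def test_detection_and_exclusion(self):
        truth = ap.default_ground_truth(
            noise_sd_pA=0.0, escape_spike_probability=1.0
        )
        control, _ = ap.generate_voltage_clamp_pair(truth, n_control=6)
        flags = [
            detect_escape_spike(s, after_ms=truth.t0_ms + 1.0)
            for s in control.sweeps
        ]
        assert all(flags)  # probability 1 ⇒ every control sweep contaminated
        with pytest.raises(TraceError):
            average_condition(control, "control",
                              exclude_escape_after_ms=truth.t0_ms + 1.0)


class TestBundleIO:
    def test_round_trip_is_bit_identical(self, tmp_path):
        truth = ap.default_ground_truth(seed=7)
        control, blocker = ap.generate_voltage_clamp_pair(truth)
        merged = ap.merge_sweep_sets(control, blocker)
        p1 = ap.write_bundle(tmp_path / "b1", merged)
        loaded, _ = ap.read_bundle(p1)
        p2 = ap.write_bundle(tmp_path / "b2", loaded)
        assert bundle_checksum(p1) == bundle_checksum(p2)
        assert len(loaded) == len(merged)
        assert loaded.sweeps[0].holding_mV == merged.sweeps[0].holding_mV

    def test_empty_bundle_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        (tmp_path / "empty" / "manifest.txt").write_text(
            "cell_id = x\nstimulus = y\nn_sweeps = 0\ndt_ms = 0.02\n"
            "signal_kind = current_pA\n"
        )
        with pytest.raises(TraceError, match="no sweeps"):
            ap.read_bundle(tmp_path / "empty")


class TestAnalyzePairPipeline:
    def test_noiseless_truth_recovered(self, noiseless_pair):
        truth, control, blocker = noiseless_pair
        out = ap.analyze_pair(ap.merge_sweep_sets(control, blocker),
                              e_gaba_mV=-73.0, e_ahp_mV=-95.0)
        aut, ahp = out["autaptic"], out["ahp"]
        assert aut.peak_nS == pytest.approx(truth.aut_peak_nS, rel=0.005)
        assert aut.decay.tau_ms == pytest.approx(truth.aut_tau_ms, rel=0.005)
        assert aut.delay_to_peak_ms == pytest.approx(truth.aut_delay_ms,
                                                     abs=0.05)
        assert ahp.peak_nS == pytest.approx(truth.ahp_peak_nS, rel=0.02)
        assert ahp.decay.tau_ms == pytest.approx(truth.ahp_tau_ms, rel=0.01)
        assert ahp.delay_to_peak_ms == pytest.approx(truth.ahp_delay_ms,
                                                     abs=0.06)

    def test_holding_potential_invariance(self):
        peaks = []
        for vh in (-43.0, -55.0):
            truth = ap.default_ground_truth(noise_sd_pA=0.0, holding_mV=vh)
            c, b = ap.generate_voltage_clamp_pair(truth)
            iso = ap.analyze_pair(ap.merge_sweep_sets(c, b), -73.0, -95.0)
            peaks.append(iso["autaptic"].peak_nS)
        assert abs(peaks[0] - peaks[1]) / peaks[0] < 0.005
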