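"""Gait events, real-time velocity filtering and the COM reference learner."""

import numpy as np
import pytest
from scipy import signal as sig

from ankleflex.com_reference import (
    ComReference,
    com_deviation,
    design_com_filter,
    detect_heel_strike,
    filter_com_velocity,
    resample_to_phase,
    update_reference,
)
from ankleflex.muscle import GRAVITY
from ankleflex.synthetic import GeneratorConfig, grf_template, com_deviation_response


class TestHeelStrikeDetection:
    def test_square_wave_one_event_per_period(self):
        fs = 1000.0
        i = np.arange(5000)
        fz = np.where((i % 1000) >= 400, 700.0, 0.0)
        ev = detect_heel_strike(fz, fs)
        np.testing.assert_array_equal(ev.heel_strikes, [400, 1400, 2400, 3400, 4400])
        # toe-offs at the falling edges
        np.testing.assert_array_equal(ev.toe_offs, [1000, 2000, 3000, 4000])

    def test_constant_force_raises(self):
        with pytest.raises(ValueError, match="no heel strikes"):
            detect_heel_strike(np.full(1000, 600.0), 1000.0)

    def test_noisy_synthetic_grf_within_one_sample(self):
        """Events on a noisy template land within +-1 sample of the template's
        threshold crossings."""
        fs, T, mass = 1000.0, 1.4, 70.0
        t = np.arange(0, 3 * T, 1 / fs)
        phase = 100.0 * (t / T)
        fz = grf_template(phase, mass)
        truth = detect_heel_strike(fz, fs).heel_strikes
        rng = np.random.default_rng(7)
        noisy = np.maximum(fz + rng.normal(0, 2.0, len(fz)), 0.0)
        found = detect_heel_strike(noisy, fs).heel_strikes
        assert len(found) == len(truth)
        assert np.max(np.abs(found - truth)) <= 1

    def test_phase_resets_at_heel_strikes(self):
        fs = 1000.0
        t = np.arange(0, 4.0, 1 / fs)
        fz = np.where((t % 1.0) >= 0.4, 700.0, 0.0)
        ev = detect_heel_strike(fz, fs)
        for hs in ev.heel_strikes:
            assert ev.phase[hs] == pytest.approx(0.0, abs=1e-9)
        assert np.all((ev.phase >= 0) & (ev.phase < 100))


class TestVelocityFilter:
    def test_constant_position_gives_zero_velocity(self):
        out = filter_com_velocity(np.full(4000, 1.23), 1000.0)
        assert np.max(np.abs(out[1000:])) < 1e-9

    @pytest.mark.parametrize("freq", [10.0, 1.0])
    def test_sinusoid_gain_matches_designed_filter(self, freq):
        """Output amplitude = 2*pi*f*A times the designed filter's gain at f."""
        fs, A = 1000.0, 0.01
        t = np.arange(0, 8.0, 1 / fs)
        pos = A * np.sin(2 * np.pi * freq * t)
        out = filter_com_velocity(pos, fs)
        sos = design_com_filter(fs)
        w, h = sig.sosfreqz(sos, worN=[freq], fs=fs)
        # the backward difference also has a (near-unity) gain at low f
        diff_gain = abs(2 * np.sin(np.pi * freq / fs) * fs / (2 * np.pi * freq))
        expected = 2 * np.pi * freq * A * abs(h[0]) * diff_gain
        measured = np.max(np.abs(out[len(out) // 2 :]))
        assert measured == pytest.approx(expected, rel=0.05)

    def test_in_band_gain_near_unity_out_of_band_attenuated(self):
        sos = design_com_filter(1000.0)
        w, h = sig.sosfreqz(sos, worN=[1.0, 10.0], fs=1000.0)
        assert abs(h[1]) > 0.9  # 10 Hz in band
        assert abs(h[0]) < 0.1  # 1 Hz strongly attenuated

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            filter_com_velocity(np.zeros(100), 80.0)


class TestReferenceLearner:
    def test_six_identical_cycles_reproduce_the_cycle(self):
        ref = ComReference()
        cycle = np.sin(np.linspace(0, 2 * np.pi, 1001))
        for _ in range(6):
            update_reference(ref, cycle)
        np.testing.assert_allclose(ref.table, cycle, atol=1e-15)

    def test_arithmetic_mean_of_shifted_cycles(self):
        ref = ComReference()
        c = np.cos(np.linspace(0, 2 * np.pi, 1001))
        delta = 0.02
        for i in range(6):
            update_reference(ref, c + i * delta)
        np.testing.assert_allclose(ref.table, c + 2.5 * delta, atol=1e-12)

    def test_fifo_window_semantics(self):
        ref = ComReference()
        for i in range(6):
            update_reference(ref, np.full(1001, float(i)))
        update_reference(ref, np.full(1001, 6.0))  # pushes out cycle 0
        assert ref.table[0] == pytest.approx(np.mean([1, 2, 3, 4, 5, 6]))

    def test_perturbed_cycle_rejected_with_warning(self):
        ref = ComReference()
        update_reference(ref, np.ones(1001))
        with pytest.warns(UserWarning, match="rejected"):
            update_reference(ref, np.full(1001, 9.0), perturbed=True)
        assert ref.n_cycles == 1


class TestComDeviation:
    def _ref(self, value=0.6):
        ref = ComReference()
        ref.add_cycle(np.full(1001, value))
        return ref

    def test_zero_when_measurement_matches_reference(self):
        ref = self._ref()
        phase = np.linspace(0, 99.9, 100)
        np.testing.assert_allclose(com_deviation(np.full(100, 0.6), phase, ref), 0.0)

    def test_constant_offset_passes_through(self):
        ref = self._ref()
        dev = com_deviation(np.full(50, 0.7), np.linspace(0, 99, 50), ref)
        np.testing.assert_allclose(dev, 0.1, atol=1e-12)

    def test_uninitialized_reference_raises(self):
        with pytest.raises(RuntimeError, match="not initialized"):
            com_deviation(0.5, 10.0, ComReference())

    def test_push_pulse_gives_positive_deviation(self):
        """A forward push on the point-mass model produces a positive forward
        velocity deviation during and after the pulse."""
        cfg = GeneratorConfig(seed=0)
        dv = com_deviation_response(cfg, "push", 0.12)
        onset = int(round(cfg.onset_phase * cfg.cycle_duration / cfg.dt))
        pulse_end = onset + int(round(cfg.pulse_duration / cfg.dt))
        assert np.all(dv[onset + 2 : pulse_end + 200] > 0)
        ref = self._ref(0.62)
        phase = np.linspace(0, 99.9, len(dv))
        dev = com_deviation(0.62 + dv, phase, ref)
        np.testing.assert_allclose(dev, dv, atol=1e-12)

    def test_unperturbed_cycles_have_zero_mean_deviation(self, rng):
        """Cycles drawn from the reference distribution deviate with zero mean
        within Monte-Carlo error."""
        base = np.sin(np.linspace(0, 2 * np.pi, 1001))
        ref = ComReference()
        for _ in range(6):
            ref.add_cycle(base + rng.normal(0, 0.05, 1001))
        devs = []
        phase = np.linspace(0, 100, 1001)
        for _ in range(200):
            cyc = base + rng.normal(0, 0.05, 1001)
            devs.append(np.mean(com_deviation(cyc, phase, ref)))
        # MC error includes the (shared) sampling error of the 6-cycle reference
        bound = 3 * 0.05 * np.sqrt(1 / (6 * 1001) + 1 / (200 * 1001))
        assert abs(np.mean(devs)) < bound


class TestPhaseResampling:
    def test_idempotent_round_trip(self):
        """Resampling a cycle to the phase grid and back reproduces it within
        interpolation tolerance."""
        n = 1400
        t = np.linspace(0, 100, n)
        y = np.sin(2 * np.pi * t / 100) + 0.3 * np.cos(4 * np.pi * t / 100)
        on_grid = resample_to_phase(y)
        back = np.interp(t, np.linspace(0, 100, len(on_grid)), on_grid)
        np.testing.assert_allclose(back, y, atol=1e-4)
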