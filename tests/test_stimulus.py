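import math

import numpy as np
import pytest
import sympy

from cahomeo import ModelParameters, Simulation
from cahomeo.stimulus import (
    CalibrationError,
    Epoch,
    StimulusProgram,
    SWR_WAVEFORM_MS,
    calibrate_theta_amplitude,
    chirp,
    preset_program,
    reset_pulse,
    swr_train,
    swr_waveform,
    theta_drive,
)


class TestThetaDrive:
    def test_zero_amplitude_is_silence(self):
        t = np.linspace(0, 1000, 500)
        assert np.all(theta_drive(t, 0.0) == 0.0)

    def test_period_and_nonnegativity(self):
        t = np.linspace(0, 125.0, 2001)
        p = theta_drive(t, 1e-8, 8.0)
        assert p[0] == pytest.approx(p[-1], abs=1e-20)  # 125 ms = one 8 Hz cycle
        assert np.all(p >= 0)
        assert np.max(p) == pytest.approx(1e-8, rel=1e-6)  # peak-to-peak

    def test_mean_is_half_amplitude(self):
        t = np.arange(0, 1000.0, 0.01)  # 8 full cycles
        assert np.mean(theta_drive(t, 2e-8, 8.0)) == pytest.approx(1e-8, rel=1e-4)


class TestSWRWaveform:
    def test_printed_values(self):
        # ripple term vanishes at 40 ms (sin(2pi*6) = 0)
        assert swr_waveform(40.0) == pytest.approx(math.exp(-225.0 / 800.0),
                                                   abs=1e-4)
        assert swr_waveform(40.0) == pytest.approx(0.7548, abs=1e-4)
        # at 55 ms: 1 - 0.3 e^-0.5 sin(2pi*8.25) = 0.8180
        assert swr_waveform(55.0) == pytest.approx(0.8180, abs=1e-4)

    def test_matches_symbolic_oracle_on_grid(self):
        ts = sympy.symbols("t")
        expr = (sympy.exp(-((ts - 55) ** 2) / (2 * 20 * 20))
                - sympy.Rational(3, 10) * sympy.exp(-((ts - 40) ** 2) / (2 * 15 * 15))
                * sympy.sin(2 * sympy.pi * 150 * ts / 1000))
        f = sympy.lambdify(ts, expr, "numpy")
        grid = np.arange(0.0, 150.0001, 0.1)
        assert np.allclose(swr_waveform(grid), f(grid), rtol=0, atol=1e-12)

    def test_support_is_about_150_ms(self):
        # the sharp-wave envelope still reads 0.023 at t = 0, so the ~150 ms
        # support is asserted with a small margin outside the event window
        edges = np.concatenate([np.linspace(-50, -20.0, 100),
                                np.linspace(160.0, 300, 100)])
        assert np.all(np.abs(swr_waveform(edges)) < 0.01)
        inside = np.arange(0.0, 150.0, 0.05)
        outside = np.concatenate([np.arange(-200.0, 0.0, 0.05),
                                  np.arange(150.0, 400.0, 0.05)])
        e_in = np.sum(swr_waveform(inside) ** 2)
        e_out = np.sum(swr_waveform(outside) ** 2)
        assert e_out / (e_in + e_out) < 0.01


class TestSWRTrain:
    def test_events_repeat_identically_at_3_hz(self):
        t1 = np.linspace(0, 150, 1500)
        t2 = t1 + 1000.0 / 3.0
        a = swr_train(t1, 1e-8)
        b = swr_train(t2, 1e-8)
        assert np.allclose(a, b, atol=1e-20)
        assert np.max(a) > 0

    def test_silent_between_events_and_nonnegative(self):
        t = np.linspace(SWR_WAVEFORM_MS + 1, 1000.0 / 3.0 - 1, 200)
        assert np.all(swr_train(t, 1e-8) == 0.0)
        t_all = np.linspace(0, 2000, 5000)
        assert np.all(swr_train(t_all, 1e-8) >= 0.0)

    def test_too_fast_repeat_rejected(self):
        with pytest.raises(ValueError):
            swr_train(0.0, 1e-8, repeat_hz=10.0)
        with pytest.raises(ValueError):
            Epoch("swr", 1000.0, 1e-8, frequency=10.0)


class TestChirp:
    def test_amplitude_convention(self):
        t = np.linspace(0, 25e3, 250001)
        i = chirp(t, amplitude_pa=50.0)
        assert np.max(i) - np.min(i) == pytest.approx(100.0, rel=1e-3)

    def test_instantaneous_frequency_is_linear(self):
        # phase = 2 pi f_max t^2 / (2 span): d(phase)/dt at span/2 -> f_max/2
        span = 25e3
        t0 = span / 2
        dt = 1e-3
        dphase = (2 * math.pi * (25.0 / 1e3) * ((t0 + dt) ** 2 - t0 ** 2)
                  / (2 * span))
        f_inst = dphase / dt / (2 * math.pi) * 1e3  # Hz
        assert f_inst == pytest.approx(12.5, rel=1e-4)

    def test_integral_over_span_is_small(self):
        # net charge is a few percent of the rectified area (the slow first
        # cycles dominate the residual)
        t = np.arange(0, 25e3, 0.1)
        i = chirp(t)
        integral = np.trapezoid(i, t)
        rectified = np.trapezoid(np.abs(i), t)
        assert abs(integral) < 0.05 * rectified


class TestProgramsAndReset:
    def test_reset_pulse_clamps_voltage_exactly(self, base_params):
        sim = Simulation(base_params, dt=0.05)
        sim.state.voltage = -30.0
        rec = sim.run("reset", 1000.0, record_stride=1)
        assert np.all(rec.v == -65.0)
        # gates and calcium keep evolving toward their clamped steady state
        assert sim.state.gates[0] != pytest.approx(0.0)

    def test_reset_default_duration(self):
        assert reset_pulse().duration == 1000.0

    def test_presets_interleave_reset_before_theta_to_swr(self):
        prog = preset_program("theta-swr-theta", 1e-8, 1e-8)
        kinds = [e.kind for e in prog.epochs]
        assert kinds == ["theta", "reset", "swr", "theta"]
        prog2 = preset_program("swr-theta-swr", 1e-8, 1e-8)
        assert [e.kind for e in prog2.epochs] == ["swr", "theta", "reset", "swr"]

    def test_empty_program_rejected(self):
        with pytest.raises(ValueError):
            StimulusProgram(())

    def test_drive_is_deterministic(self, base_params):
        recs = []
        for _ in range(2):
            sim = Simulation(base_params, dt=0.05)
            recs.append(sim.run("theta", 500.0, amplitude=1e-8, record_stride=1))
        assert np.array_equal(recs[0].v, recs[1].v)
        assert np.array_equal(recs[0].ca, recs[1].ca)


class TestThetaCalibration:
    def test_minimum_amplitude_brackets_spiking(self, base_params):
        factory = lambda: Simulation(base_params, dt=0.05)
        amp = calibrate_theta_amplitude(factory, probe_ms=1000.0)

        def spikes(a):
            sim = factory()
            rec = sim.run("theta", 1000.0, amplitude=a, record_stride=1,
                          use_holding=True)
            from cahomeo.engine import detect_spikes
            times, _ = detect_spikes(rec.t, rec.v, -20.0, 2.0)
            return len(times) >= 1

        assert spikes(amp)
        assert not spikes(0.9 * amp)

    def test_more_excitable_model_needs_no_more_drive(self, base_params):
        hot = base_params.copy()
        hot.values["Na-g"] = 0.01  # top of the sodium range
        a_base = calibrate_theta_amplitude(
            lambda: Simulation(base_params, dt=0.05), probe_ms=1000.0)
        a_hot = calibrate_theta_amplitude(
            lambda: Simulation(hot, dt=0.05), probe_ms=1000.0)
        assert a_hot <= a_base * 1.02

    def test_exhausted_bracket_raises(self, passive_params):
        with pytest.raises(CalibrationError):
            calibrate_theta_amplitude(
                lambda: Simulation(passive_params, dt=0.05),
                probe_ms=500.0, upper=1e-9)
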