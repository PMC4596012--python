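import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cahomeo.biophysics import (
    CalciumGateSpec,
    ChannelSpec,
    GateSpec,
    Geometry,
    InvalidGateError,
    InvalidGeometryError,
    ModelParameters,
    PARAM_TABLE,
    boltzmann_steady_state,
    calcium_gate_steady_state,
    channel_current,
    lateral_area,
    passive_input_resistance,
)
from cahomeo.engine import Simulation, detect_spikes


class TestGeometry:
    def test_lateral_area_default_cylinder(self):
        # pi * 100 um * 100 um = 3.1416e-4 cm2
        assert lateral_area(Geometry(100.0, 100.0)) == pytest.approx(
            math.pi * 1e-4, rel=1e-12)

    def test_area_linear_in_length(self):
        a1 = lateral_area(Geometry(100.0, 100.0))
        a2 = lateral_area(Geometry(100.0, 200.0))
        assert a2 == pytest.approx(2 * a1)

    @pytest.mark.parametrize("d,l", [(0.0, 100.0), (100.0, -1.0)])
    def test_degenerate_geometry_rejected(self, d, l):
        with pytest.raises(InvalidGeometryError):
            Geometry(d, l)


class TestPassiveInputResistance:
    def test_default_cylinder_is_111_mohm(self):
        # R_m / area = 35000 / 3.1416e-4 Ohm = 111.4 MOhm
        rin = passive_input_resistance(35.0, Geometry())
        assert rin == pytest.approx(111.4, abs=0.05)

    def test_proportional_to_rm_and_inverse_in_area(self):
        g = Geometry()
        assert passive_input_resistance(70.0, g) == pytest.approx(
            2 * passive_input_resistance(35.0, g))
        gbig = Geometry(100.0, 200.0)
        assert passive_input_resistance(35.0, gbig) == pytest.approx(
            passive_input_resistance(35.0, g) / 2)


class TestGating:
    def test_boltzmann_midpoint_and_example(self):
        gate = GateSpec(-30.0, 6.0, 1.0)
        assert boltzmann_steady_state(-30.0, gate) == pytest.approx(0.5)
        # v = V1/2 + 2k -> 1/(1+e^-2)
        assert boltzmann_steady_state(-18.0, gate) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.0)), rel=1e-12)

    def test_boltzmann_saturates(self):
        gate = GateSpec(-30.0, 6.0, 1.0)
        assert boltzmann_steady_state(200.0, gate) > 0.999999
        # negative slope encodes inactivation: closes with depolarization
        inact = GateSpec(-45.0, -6.0, 1.0)
        assert boltzmann_steady_state(200.0, inact) < 1e-6

    def test_zero_slope_rejected(self):
        with pytest.raises(InvalidGateError):
            GateSpec(-30.0, 0.0, 1.0)

    @given(v=st.floats(-120, 60), vh=st.floats(-90, 20),
           k=st.floats(1.0, 20.0))
    @settings(max_examples=200, deadline=None)
    def test_boltzmann_always_a_fraction(self, v, vh, k):
        x = boltzmann_steady_state(v, GateSpec(vh, k, 1.0))
        # open interval mathematically; saturates to the closed one in floats
        assert 0.0 <= x <= 1.0
        assert 0.0 < x


    def test_calcium_gate_half_max_and_limits(self):
        spec = CalciumGateSpec(1.4e-4, 196.8, hill_coefficient=4)
        assert calcium_gate_steady_state(1.4e-4, spec) == pytest.approx(0.5)
        assert calcium_gate_steady_state(0.0, spec) == 0.0
        assert calcium_gate_steady_state(1.0, spec) > 0.999
        with pytest.raises(ValueError):
            calcium_gate_steady_state(-1e-6, spec)


class TestChannelCurrent:
    def test_ohmic_kdr_example(self):
        # g * n * (v - E_K): 0.003 * 1 * (0 - (-90)) = 0.27 mA/cm2
        spec = ChannelSpec("KDR", 0.003, (GateSpec(13.0, 8.0, 22.29),), -90.0)
        assert channel_current(spec, 0.0, (1.0,)) == pytest.approx(0.27)

    def test_zero_conductance_and_reversal(self):
        spec = ChannelSpec("KDR", 0.0, (GateSpec(13.0, 8.0, 22.29),), -90.0)
        assert channel_current(spec, 0.0, (0.5,)) == 0.0
        spec2 = ChannelSpec("KDR", 0.003, (GateSpec(13.0, 8.0, 22.29),), -90.0)
        assert channel_current(spec2, -90.0, (0.5,)) == 0.0

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            ChannelSpec("KDRX", 0.003, (), -90.0)


class TestTable:
    def test_all_48_parameters_present(self):
        assert len(PARAM_TABLE) == 48

    def test_base_model_has_every_symbol(self, base_params):
        assert set(base_params.values) == set(PARAM_TABLE)

    def test_leak_conductance_from_rm(self, base_params):
        assert base_params.g_leak == pytest.approx(1.0 / 35e3)


class TestPassiveDynamics:
    def test_step_response_matches_ohms_law(self, passive_sim):
        # 10 pA across 111.4 MOhm -> 1.114 mV steady deflection
        rec = passive_sim.run("current_step", 300.0, amplitude=10.0,
                              record_stride=1)
        assert rec.v[-1] - (-65.0) == pytest.approx(1.114, rel=0.01)

    def test_relaxation_time_constant_is_rm_cm(self, passive_sim):
        # R_m * C_m = 35 kOhm cm2 * 1 uF/cm2 = 35 ms
        from scipy.optimize import curve_fit
        rec = passive_sim.run("current_step", 300.0, amplitude=10.0,
                              record_stride=1)
        t = rec.t - rec.t[0] + passive_sim.dt

        def charging(t, a, tau):
            return a * (1 - np.exp(-t / tau))

        (a, tau), _ = curve_fit(charging, t, rec.v + 65.0, p0=[1.0, 30.0])
        assert tau == pytest.approx(35.0, rel=0.02)

    def test_positive_current_depolarizes(self, passive_sim):
        rec = passive_sim.run("current_step", 100.0, amplitude=20.0,
                              record_stride=1)
        assert rec.v[-1] > -65.0

    def test_rest_is_a_fixed_point(self, passive_sim):
        rec = passive_sim.run("silent", 500.0, record_stride=1)
        assert np.max(np.abs(rec.v + 65.0)) < 1e-9


class TestActiveDynamics:
    def test_gates_stay_fractions_through_firing(self, base_params):
        sim = Simulation(base_params, dt=0.05)
        sim.run("current_step", 500.0, amplitude=250.0, record_stride=1)
        assert np.all(sim.state.gates >= 0.0)
        assert np.all(sim.state.gates <= 1.0)

    def test_exponential_gate_update_matches_closed_form(self, base_params):
        # under voltage clamp each gate relaxes as x_inf + (x0-x_inf)e^(-t/tau)
        sim = Simulation(base_params, dt=0.05)
        x0 = sim.state.gates.copy()
        clamp = -30.0
        sim.run("reset", 50.0, clamp_mv=clamp, record_stride=1)
        gb, tau = sim._gb, sim._tau
        xinf = 1.0 / (1.0 + np.exp(-(clamp - gb[:, 0]) / gb[:, 1]))
        expected = xinf + (x0[:15] - xinf) * np.exp(-50.0 / tau[:15])
        assert np.allclose(sim.state.gates[:15], expected, rtol=1e-9, atol=1e-12)

    def test_dt_convergence_under_theta_drive(self, base_params):
        traces = {}
        for dt in (0.05, 0.025):
            sim = Simulation(base_params, dt=dt)
            stride = int(round(1.0 / dt))
            rec = sim.run("theta", 1000.0, amplitude=1.1e-8,
                          record_stride=stride, use_holding=True)
            traces[dt] = rec.v
        rms = np.sqrt(np.mean((traces[0.05] - traces[0.025]) ** 2))
        assert rms < 0.5

    def test_spike_detection_refractory(self):
        t = np.arange(0, 20, 0.1)
        v = np.full_like(t, -65.0)
        v[(t > 5) & (t < 6)] = 10.0  # one spike
        v[(t > 6.5) & (t < 7)] = 5.0  # within refractory of return? separate crossing
        times, peaks = detect_spikes(t, v, -20.0, 2.0)
        assert len(times) == 1
        assert peaks[0] == pytest.approx(10.0)
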