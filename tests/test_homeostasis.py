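import numpy as np
import pytest

from cahomeo import ModelParameters, Simulation
from cahomeo.biophysics import default_conductances
from cahomeo.constants import CHANNEL_NAMES
from cahomeo.engine import IntegrationError
from cahomeo.homeostasis import (
    HomeostasisEngine,
    HomeostasisParams,
    classify_robust_plastic,
    derive_time_constants,
    evolve,
    percent_changes,
    run_to_steady_state,
)
from cahomeo.stimulus import Epoch

THETA_AMP = 1.15e-8  # calibrated minimum spiking amplitude of the base model


class TestTimeConstants:
    def test_table_default_ratio_example(self):
        g = np.full(12, 0.007)
        g[CHANNEL_NAMES.index("KDR")] = 0.003
        tau = derive_time_constants(g, tau_na=10.0)
        assert tau[CHANNEL_NAMES.index("KDR")] == pytest.approx(23.333, abs=1e-2)

    def test_equal_conductances_equal_taus(self):
        tau = derive_time_constants(np.full(12, 1e-3), tau_na=10.0)
        assert np.allclose(tau, 10.0)

    def test_tau_g_product_invariant(self, base_params):
        g = default_conductances(base_params)
        tau = derive_time_constants(g, tau_na=10.0)
        assert np.allclose(tau * g, tau[1] * g[1], rtol=1e-12)

    def test_zero_reference_conductance_rejected(self):
        g = np.full(12, 1e-3)
        g[3] = 0.0
        with pytest.raises(ValueError, match="KA"):
            derive_time_constants(g)


class TestControllerUpdate:
    def test_fixed_point_at_target(self):
        m0 = np.full(12, 1e-3)
        g0 = np.full(12, 1e-3)
        tau = np.full(12, 10.0)
        m, g = evolve(m0, g0, 2e-4, tau, 10.0, 2e-4, dt=0.025)
        assert np.array_equal(m, m0)
        assert np.allclose(g, g0)

    def test_common_error_drives_all_mrnas_up(self):
        m0 = np.zeros(12)
        tau = derive_time_constants(np.linspace(1e-4, 1e-2, 12))
        m, _ = evolve(m0, np.zeros(12), 1e-4, tau, 10.0, 2e-4, dt=1.0)
        assert np.all(m > 0)

    def test_increments_proportional_to_inverse_tau(self):
        # one transcription factor: m_i trajectories are scaled copies
        tau = derive_time_constants(np.linspace(1e-4, 1e-2, 12))
        m, _ = evolve(np.zeros(12), np.zeros(12), 1e-4, tau, 10.0, 2e-4, dt=1.0)
        ratio = m * tau
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_translation_relaxes_to_mrna(self):
        m0 = np.full(12, 5e-3)
        g = np.zeros(12)
        for _ in range(10000):
            _, g = evolve(m0, g, 2e-4, np.full(12, 10.0), 10.0, 2e-4, dt=0.1)
        assert np.allclose(g, m0, rtol=1e-3)

    def test_nonnegativity_floor(self):
        m, g = evolve(np.zeros(12), np.zeros(12), 5e-4, np.full(12, 1.0),
                      10.0, 2e-4, dt=100.0)  # calcium far above target
        assert np.all(m == 0.0) and np.all(g >= 0.0)


@pytest.fixture(scope="module")
def theta_run(base_params):
    sim = Simulation(base_params, dt=0.05)
    engine = HomeostasisEngine(base_params,
                               HomeostasisParams(tau_scale=0.5, seed=1))
    engine.reset(sim)
    return run_to_steady_state(
        sim, engine, Epoch("theta", 40_000.0, THETA_AMP, 8.0))


class TestSteadyState:
    def test_calcium_reaches_target(self, theta_run):
        assert theta_run.mean_calcium == pytest.approx(2e-4, rel=0.05)

    def test_conductances_track_mrna(self, base_params):
        sim = Simulation(base_params, dt=0.05)
        engine = HomeostasisEngine(base_params,
                                   HomeostasisParams(tau_scale=0.5, seed=1))
        engine.reset(sim)
        run_to_steady_state(sim, engine,
                            Epoch("theta", 20_000.0, THETA_AMP, 8.0))
        # g follows m with a 5 ms translation lag: equal well within 1%
        assert np.allclose(sim.g12, engine.mrna, rtol=0.01)

    def test_tau_scale_invariance_of_steady_state(self, base_params, theta_run):
        sim = Simulation(base_params, dt=0.05)
        engine = HomeostasisEngine(base_params,
                                   HomeostasisParams(tau_scale=1.0, seed=1))
        engine.reset(sim)
        full = run_to_steady_state(
            sim, engine, Epoch("theta", 40_000.0, THETA_AMP, 8.0))
        rel = np.abs(full.conductances - theta_run.conductances) \
            / np.abs(full.conductances)
        assert np.max(rel) < 0.02

    def test_target_tracking(self, base_params):
        sim = Simulation(base_params, dt=0.05)
        engine = HomeostasisEngine(
            base_params, HomeostasisParams(ca_target=1e-4, tau_scale=0.5, seed=1))
        engine.reset(sim)
        res = run_to_steady_state(sim, engine,
                                  Epoch("theta", 40_000.0, THETA_AMP, 8.0))
        assert res.mean_calcium == pytest.approx(1e-4, rel=0.05)

    def test_windup_guard_raises(self, base_params):
        # a tight safety ceiling turns the growth transient into a windup
        sim = Simulation(base_params, dt=0.05)
        cfg = HomeostasisParams(tau_scale=0.5, seed=1, windup_factor=1e-3)
        engine = HomeostasisEngine(base_params, cfg)
        engine.reset(sim)
        with pytest.raises(IntegrationError, match="windup"):
            run_to_steady_state(sim, engine,
                                Epoch("theta", 40_000.0, THETA_AMP, 8.0))


class TestClassification:
    def test_identical_vectors_robust(self):
        g = np.linspace(1e-4, 1e-2, 12)
        assert classify_robust_plastic(g, g.copy()) == "robust"

    def test_large_single_channel_change_plastic(self):
        g1 = np.linspace(1e-4, 1e-2, 12)
        g3 = g1.copy()
        g3[4] *= 1.5
        assert classify_robust_plastic(g1, g3) == "plastic"
        assert classify_robust_plastic(g1, g3, threshold=np.inf) == "robust"

    def test_percent_change_definition(self):
        g1 = np.full(12, 2.0)
        g3 = np.full(12, 3.0)
        assert np.allclose(percent_changes(g1, g3), 50.0)

    def test_zero_reference_channel_excluded(self):
        g1 = np.ones(12)
        g1[0] = 0.0
        g3 = np.ones(12) * 1.05
        pct = percent_changes(g1, g3)
        assert np.isnan(pct[0])
        assert classify_robust_plastic(g1, g3) == "robust"
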