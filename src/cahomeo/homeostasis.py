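"""Integral-control calcium homeostasis: transcription and translation.

A single calcium sensor drives all 12 channels: each mRNA m_i integrates
the error between the calcium target and the cytosolic (outer-shell)
concentration,

    tau_i dm_i/dt = [Ca]_tgt - [Ca]_c,

and each conductance relaxes toward its mRNA with the translation time
constant,

    tau_g dg_i/dt = m_i - g_i.

Because one error signal feeds every mRNA, increments of all m_i are
proportional (ratio tau_j/tau_i); the transcription time constants are
derived from a reference model's conductances through

    tau_j / tau_i = g_i / g_j,

anchored at tau_Na = 10 ms, so high-conductance channels respond fastest.
At any steady state the integral controller forces the mean cytosolic
calcium to the target exactly; the conductance values this is achieved
with are free — hence calcium homeostasis without "channelostasis".

Uniformly rescaling every tau (tau_i and tau_g) changes the time course
but not the steady state, which licenses the scaled-down runs used in
tests (``tau_scale`` < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .biophysics import CHANNEL_NAMES, PARAM_TABLE, ModelParameters, default_conductances
from .calcium import CalciumParams
from .engine import IntegrationError, Simulation, detect_spikes
from .measurements import MeasurementVector, measure_all
from .stimulus import Epoch, StimulusProgram, reset_pulse
from .synapses import SynapseParams

__all__ = [
    "HomeostasisParams",
    "HomeostasisEngine",
    "SwitchResult",
    "derive_time_constants",
    "evolve",
    "run_to_steady_state",
    "run_switch_protocol",
    "classify_robust_plastic",
]


@dataclass(frozen=True)
class HomeostasisParams:
    """Controller constants (mM, ms)."""

    ca_target: float = 2e-4  # mM (200 nM)
    tau_translation: float = 10.0  # ms
    tau_na_anchor: float = 10.0  # ms
    tau_scale: float = 1.0  # uniform rescaling of all taus
    init_scale: float = 0.01  # initial m, g as fraction of table defaults
    windup_factor: float = 100.0  # ceiling = factor * range max
    seed: int | None = None

    def __post_init__(self):
        if self.ca_target <= 0:
            raise ValueError("ca_target must be > 0")
        if min(self.tau_translation, self.tau_na_anchor, self.tau_scale) <= 0:
            raise ValueError("time constants and tau_scale must be > 0")


def derive_time_constants(reference_conductances: np.ndarray,
                          tau_na: float = 10.0) -> np.ndarray:
    """Transcription taus from a reference conductance vector.

    tau_i * g_i is constant across channels, anchored at the sodium
    channel: tau_i = tau_na * g_Na / g_i.
    """
    g = np.asarray(reference_conductances, dtype=float)
    if g.shape != (12,):
        raise ValueError("expected a 12-vector of conductances")
    if np.any(g <= 0):
        bad = [CHANNEL_NAMES[i] for i in np.flatnonzero(g <= 0)]
        raise ValueError(f"zero/negative reference conductance for {bad}")
    g_na = g[CHANNEL_NAMES.index("NaF")]
    return tau_na * g_na / g


def evolve(mrna: np.ndarray, conductances: np.ndarray, ca: float,
           tau_mrna: np.ndarray, tau_g: float, ca_target: float,
           dt: float):
    """One controller step (reference implementation of the update rule).

    The integration kernel applies the identical update inline; this
    function is the readable, unit-tested form.  Returns (mrna, g).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    err = ca_target - ca
    m = np.maximum(mrna + dt * err / tau_mrna, 0.0)
    g = conductances + (m - conductances) * (1.0 - math.exp(-dt / tau_g))
    g = np.maximum(g, 0.0)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(g))):
        bad = CHANNEL_NAMES[int(np.flatnonzero(~np.isfinite(m * g))[0])]
        raise IntegrationError(f"non-finite homeostasis state for channel {bad}")
    return m, g


#: upper bound of each conductance's testing range, canonical units
_RANGE_MAX = {
    "Leak": 1.0 / (PARAM_TABLE["R_m"].low * 1e3),
    "NaF": PARAM_TABLE["Na-g"].high * PARAM_TABLE["Na-g"].scale,
    "KDR": PARAM_TABLE["DR-g"].high * PARAM_TABLE["DR-g"].scale,
    "KA": PARAM_TABLE["A-g"].high * PARAM_TABLE["A-g"].scale,
    "KM": PARAM_TABLE["M-g"].high * PARAM_TABLE["M-g"].scale,
    "HCN": PARAM_TABLE["h-g"].high * PARAM_TABLE["h-g"].scale,
    "CaT": PARAM_TABLE["T-g"].high * PARAM_TABLE["T-g"].scale,
    "CaR": PARAM_TABLE["R-g"].high * PARAM_TABLE["R-g"].scale,
    "CaN": PARAM_TABLE["N-g"].high * PARAM_TABLE["N-g"].scale,
    "CaL": PARAM_TABLE["L-g"].high * PARAM_TABLE["L-g"].scale,
    "SK": PARAM_TABLE["SK-g"].high * PARAM_TABLE["SK-g"].scale,
    "BK": PARAM_TABLE["BK-g"].high * PARAM_TABLE["BK-g"].scale,
}


class HomeostasisEngine:
    """Mutable controller state bound to one model's reference conductances.

    Construct from a (valid) model; the transcription taus come from that
    model's conductances, and the initial mRNAs/conductances are
    randomized "very low" (uniform in [0, init_scale * table default]).
    """

    def __init__(self, params: ModelParameters,
                 config: HomeostasisParams | None = None):
        self.config = config or HomeostasisParams()
        cfg = self.config
        ref = default_conductances(params)
        self.tau_mrna = derive_time_constants(ref, cfg.tau_na_anchor) * cfg.tau_scale
        self.tau_translation = cfg.tau_translation * cfg.tau_scale
        self.ca_target = cfg.ca_target
        self.g_ceiling = cfg.windup_factor * np.array(
            [_RANGE_MAX[name] for name in CHANNEL_NAMES])
        rng = np.random.default_rng(cfg.seed)
        defaults = default_conductances(ModelParameters())
        self.mrna = rng.uniform(0.0, cfg.init_scale * defaults)
        self.initial_conductances = rng.uniform(0.0, cfg.init_scale * defaults)

    def reset(self, sim: Simulation) -> None:
        """Install the low initial conductances into a simulation."""
        sim.g12[:] = self.initial_conductances


@dataclass
class EpochResult:
    kind: str
    duration: float
    conductances: np.ndarray  # steady-state g12
    mean_calcium: float  # mM, trailing-window mean
    converged: bool
    firing_rate: float  # Hz over the trailing window
    depolarization_block: bool
    measurements: MeasurementVector | None = None
    g_trajectory: np.ndarray | None = None
    ca_trace: np.ndarray | None = None
    t_trace: np.ndarray | None = None


@dataclass
class SwitchResult:
    sequence: str
    epochs: list[EpochResult]
    classification: str | None = None


def run_to_steady_state(sim: Simulation, engine: HomeostasisEngine,
                        epoch: Epoch, *, tol: float = 1e-3,
                        check_window: float = 1000.0,
                        max_duration: float | None = None,
                        record_ms: float = 1.0,
                        measure: bool = False) -> EpochResult:
    """Drive one afferent-activity epoch until the conductances settle.

    Integration proceeds in windows of ``check_window`` ms; the epoch ends
    when the relative change of every window-averaged conductance falls
    below ``tol``, or when ``max_duration`` (default: the epoch duration)
    elapses.  Returns the steady state, the mean cytosolic calcium over
    the final window, the firing rate there, and optionally a frozen-model
    measurement vector.
    """
    max_duration = epoch.duration if max_duration is None else max_duration
    window = min(check_window, max_duration)
    prev_mean = None
    g_traj, ca_parts, t_parts = [], [], []
    elapsed = 0.0
    converged = False
    last_rec = None
    while elapsed < max_duration - 1e-9:
        dur = min(window, max_duration - elapsed)
        rec = sim.run_epoch(replace_duration(epoch, dur), homeostasis=engine,
                            record_stride=max(1, int(round(record_ms / sim.dt))),
                            g_record_ms=record_ms)
        last_rec = rec
        g_traj.append(rec.g)
        ca_parts.append(rec.ca)
        t_parts.append(rec.t)
        elapsed += dur
        mean_g = rec.g.mean(axis=0)
        if prev_mean is not None and dur >= window - 1e-9:
            denom = np.maximum(np.abs(prev_mean), 1e-12)
            if np.max(np.abs(mean_g - prev_mean) / denom) < tol:
                converged = True
                break
        prev_mean = mean_g
    ca_trace = np.concatenate(ca_parts)
    t_trace = np.concatenate(t_parts)
    tail = t_trace >= t_trace[-1] - window
    mean_ca = float(ca_trace[tail].mean())
    thr = sim.params.kinetics["spike_threshold"]
    refr = sim.params.kinetics["spike_refractory"]
    times, _ = detect_spikes(last_rec.t, last_rec.v, thr, refr)
    rate = len(times) / (last_rec.t[-1] - last_rec.t[0]) * 1e3
    v_tail = last_rec.v
    depol_block = bool(len(times) == 0 and np.mean(v_tail) > -40.0)
    mv = None
    if measure:
        mv = measure_all(sim)
    return EpochResult(epoch.kind, elapsed, sim.g12.copy(), mean_ca, converged,
                       rate, depol_block, mv, np.vstack(g_traj), ca_trace, t_trace)


def replace_duration(epoch: Epoch, duration: float) -> Epoch:
    return Epoch(epoch.kind, duration, epoch.amplitude, epoch.frequency,
                 epoch.ripple_frequency)


def run_switch_protocol(params: ModelParameters, sequence: str,
                        theta_amplitude: float, swr_amplitude: float, *,
                        homeostasis: HomeostasisParams | None = None,
                        calcium_params: CalciumParams | None = None,
                        synapse: SynapseParams | None = None,
                        epoch_ms: float = 150e3, reset_ms: float = 1000.0,
                        dt: float = 0.025, tol: float = 1e-3,
                        check_window: float = 1000.0,
                        max_epoch_ms: float | None = None,
                        measure: bool = False,
                        robust_threshold: float = 10.0) -> SwitchResult:
    """Three-epoch activity-switch experiment with homeostatic evolution.

    ``sequence`` is ``theta-swr-theta`` or ``swr-theta-swr``.  Every
    theta -> SWR transition is preceded by a reset pulse (voltage clamped
    to rest) to avoid depolarization-induced block.  Epochs 1 and 3
    receive identical drive; the robust/plastic classification compares
    their steady-state conductances.
    """
    kinds = {"theta-swr-theta": ("theta", "swr", "theta"),
             "swr-theta-swr": ("swr", "theta", "swr")}
    if sequence not in kinds:
        raise ValueError(f"unknown sequence {sequence!r}")
    engine = HomeostasisEngine(params, homeostasis)
    sim = Simulation(params, calcium_params=calcium_params, synapse=synapse, dt=dt)
    engine.reset(sim)
    amp = {"theta": theta_amplitude, "swr": swr_amplitude}
    freq = {"theta": 8.0, "swr": 3.0}
    results: list[EpochResult] = []
    prev = None
    for kind in kinds[sequence]:
        if prev == "theta" and kind == "swr":
            sim.run_epoch(reset_pulse(reset_ms))
        epoch = Epoch(kind, epoch_ms, amp[kind], freq[kind])
        try:
            res = run_to_steady_state(
                sim, engine, epoch, tol=tol, check_window=check_window,
                max_duration=max_epoch_ms or epoch_ms, measure=measure)
        except IntegrationError as exc:
            return SwitchResult(sequence, results, f"aborted: {exc}")
        results.append(res)
        prev = kind
    label = classify_robust_plastic(results[0].conductances,
                                    results[2].conductances,
                                    threshold=robust_threshold)
    return SwitchResult(sequence, results, label)


def percent_changes(g_first: np.ndarray, g_third: np.ndarray) -> np.ndarray:
    """Per-channel 100*(g3 - g1)/g1; NaN where g1 is zero."""
    g1 = np.asarray(g_first, dtype=float)
    g3 = np.asarray(g_third, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (g3 - g1) / g1
    pct[g1 == 0] = np.nan
    return pct


def classify_robust_plastic(g_first: np.ndarray, g_third: np.ndarray,
                            threshold: float = 10.0) -> str:
    """'robust' iff no channel changed by more than ``threshold`` percent.

    Channels with zero reference conductance are excluded (with a
    warning-carrying NaN in :func:`percent_changes`).
    """
    pct = percent_changes(g_first, g_third)
    finite = pct[np.isfinite(pct)]
    if finite.size == 0:
        return "robust"
    return "robust" if np.max(np.abs(finite)) <= threshold else "plastic"
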