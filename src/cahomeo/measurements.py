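"""The seven intrinsic measurements and their probe protocols.

Excitability: firing rate at 250 pA (f250, twice the spike count of a
500 ms step), action-potential amplitude (V_AP, last spike peak above the
-65 mV rest), input resistance (R_in, slope of the steady-state V-I
relation for -50..+50 pA steps).  Intrinsic response dynamics from a 25 s
chirp (0-25 Hz, 50 pA amplitude): maximum impedance |Z|_max, resonance
frequency f_R, resonance strength Q = |Z(f_R)|/|Z(0.5 Hz)|, and total
inductive phase Phi_L (integral of the positive part of the impedance
phase over the band).

Probes run on a frozen copy of the model (drive off, holding current
pinning rest at -65 mV); measurements on the same model are therefore
deterministic and repeatable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .engine import Simulation, detect_spikes

__all__ = [
    "MeasurementVector",
    "ValidationBounds",
    "CA1_VALIDATION_BOUNDS",
    "measure_f250",
    "measure_vap",
    "measure_rin",
    "impedance_profile",
    "resonance_measures",
    "measure_all",
    "validate",
]

IMPEDANCE_BAND = (0.5, 25.0)  # Hz


@dataclass(frozen=True)
class MeasurementVector:
    f250: float  # Hz
    v_ap: float  # mV; NaN if the model never spikes at 250 pA
    r_in: float  # MOhm
    z_max: float  # MOhm
    f_r: float  # Hz
    q: float
    phi_l: float  # rad Hz

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ValidationBounds:
    """Inclusive per-measurement (lower, upper) acceptance windows."""

    f250: tuple[float, float]
    v_ap: tuple[float, float]
    r_in: tuple[float, float]
    z_max: tuple[float, float]
    f_r: tuple[float, float]
    q: tuple[float, float]
    phi_l: tuple[float, float]

    def __post_init__(self):
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if lo >= hi:
                raise ValueError(f"bounds for {f.name} must satisfy lower < upper")


#: Experimental validation windows for CA1 pyramidal neurons.
CA1_VALIDATION_BOUNDS = ValidationBounds(
    f250=(10.0, 35.0),
    v_ap=(90.0, 110.0),
    r_in=(50.0, 90.0),
    z_max=(50.0, 110.0),
    f_r=(2.0, 5.5),
    q=(1.01, 1.5),
    phi_l=(0.0, 0.15),
)


def _fresh(sim: Simulation) -> Simulation:
    """Probe copy: same parameters and conductances, state reset to rest."""
    out = Simulation(sim.params, sim.capar, sim.synapse, dt=sim.dt)
    out.g12 = sim.g12.copy()
    out.state = out.rest_state()
    out.hold_pa = out.holding_current()
    return out


def _step_response(sim: Simulation, amp_pa: float, duration: float = 500.0):
    probe = _fresh(sim)
    rec = probe.run("current_step", duration, amplitude=amp_pa, record_stride=1)
    return rec


def measure_f250(sim: Simulation, return_trace: bool = False):
    """Firing rate (Hz) at a 250 pA, 500 ms step: twice the spike count."""
    rec = _step_response(sim, 250.0)
    thr = sim.params.kinetics["spike_threshold"]
    refr = sim.params.kinetics["spike_refractory"]
    times, peaks = detect_spikes(rec.t, rec.v, thr, refr)
    f250 = 2.0 * len(times)
    if return_trace:
        return f250, rec, times, peaks
    return f250


def measure_vap(sim: Simulation) -> float:
    """Last-spike peak above rest (-65 mV) at 250 pA; NaN if no spikes."""
    _, _, times, peaks = measure_f250(sim, return_trace=True)
    if len(peaks) == 0:
        return math.nan
    return float(peaks[-1] - sim.params.kinetics["v_rest"])


def measure_rin(sim: Simulation, currents_pa=None, duration: float = 500.0,
                steady_window: float = 50.0):
    """Input resistance (MOhm): slope of the steady-state V-I relation.

    Current steps of -50..+50 pA in 10 pA increments; the steady-state
    deflection is the mean of the trailing 50 ms of each step.  Returns
    (r_in, spiked) -- ``spiked`` flags suprathreshold contamination of the
    subthreshold probe.
    """
    if currents_pa is None:
        currents_pa = np.arange(-50.0, 51.0, 10.0)
    thr = sim.params.kinetics["spike_threshold"]
    v_rest = sim.params.kinetics["v_rest"]
    deflections = np.empty(len(currents_pa))
    spiked = False
    for i, amp in enumerate(currents_pa):
        rec = _step_response(sim, amp, duration)
        if np.any(rec.v >= thr):
            spiked = True
        tail = rec.t >= rec.t[-1] - steady_window
        deflections[i] = np.mean(rec.v[tail]) - v_rest
    slope = np.polyfit(currents_pa, deflections, 1)[0]  # mV/pA == GOhm
    return float(slope * 1e3), spiked


def impedance_profile(sim: Simulation, amplitude_pa: float = 50.0,
                      f_max: float = 25.0, span_ms: float = 25e3,
                      record_stride: int | None = None):
    """Impedance magnitude and phase from a chirp probe.

    Z(f) = FFT(v)/FFT(i) on the recorded grid, restricted to the
    0.5-25 Hz band; |Z| in MOhm.  Returns (freqs, |Z|, phase, spiked).
    """
    probe = _fresh(sim)
    if record_stride is None:
        record_stride = max(1, int(round(0.5 / probe.dt)))  # 0.5 ms grid
    rec = probe.run("chirp", span_ms, amplitude=amplitude_pa, f_max=f_max,
                    span_ms=span_ms, record_stride=record_stride)
    spiked = bool(np.any(rec.v >= sim.params.kinetics["spike_threshold"]))
    dt_s = (rec.t[1] - rec.t[0]) * 1e-3
    v_f = np.fft.rfft(rec.v - np.mean(rec.v))
    i_f = np.fft.rfft(rec.i_inj - np.mean(rec.i_inj))
    freqs = np.fft.rfftfreq(len(rec.v), dt_s)
    band = (freqs >= IMPEDANCE_BAND[0]) & (freqs <= min(IMPEDANCE_BAND[1], f_max))
    z = v_f[band] / i_f[band]  # mV/pA == GOhm
    return freqs[band], np.abs(z) * 1e3, np.angle(z), spiked


def resonance_measures(freqs: np.ndarray, zmag: np.ndarray,
                       phase: np.ndarray):
    """(f_r, z_max, q, phi_l) from an impedance profile on the probe band.

    f_r is the argmax of |Z|; Q references |Z| at the low edge (0.5 Hz) so
    Q >= 1 by construction; Phi_L is the trapezoid integral of the positive
    part of the phase profile (rad Hz).
    """
    k = int(np.argmax(zmag))
    f_r = float(freqs[k])
    z_max = float(zmag[k])
    q = z_max / float(zmag[0])
    pos = np.clip(phase, 0.0, None)
    phi_l = float(np.trapezoid(pos, freqs))
    return f_r, z_max, q, phi_l


def measure_all(sim: Simulation) -> MeasurementVector:
    """All seven intrinsic measurements of a frozen model."""
    f250, _, times, peaks = measure_f250(sim, return_trace=True)
    v_rest = sim.params.kinetics["v_rest"]
    v_ap = float(peaks[-1] - v_rest) if len(peaks) else math.nan
    r_in, rin_spiked = measure_rin(sim)
    freqs, zmag, phase, chirp_spiked = impedance_profile(sim)
    f_r, z_max, q, phi_l = resonance_measures(freqs, zmag, phase)
    if rin_spiked:
        r_in = math.nan
    if chirp_spiked:
        z_max = f_r = q = phi_l = math.nan
    return MeasurementVector(f250, v_ap, r_in, z_max, f_r, q, phi_l)


def validate(m: MeasurementVector,
             bounds: ValidationBounds = CA1_VALIDATION_BOUNDS):
    """(valid, per-measurement verdicts); bounds inclusive, NaN invalid."""
    verdicts = {}
    for f in fields(MeasurementVector):
        val = getattr(m, f.name)
        lo, hi = getattr(bounds, f.name)
        verdicts[f.name] = bool(np.isfinite(val) and lo <= val <= hi)
    return all(verdicts.values()), verdicts
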