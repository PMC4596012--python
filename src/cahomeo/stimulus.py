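"""Afferent drive programs: theta, sharp-wave ripples, probes, sequences.

Two behaviorally distinct synaptic drives are modeled, both delivered as
time-varying AMPAR/NMDAR permeability (the NMDAR permeability follows the
AMPAR one through the NAR ratio):

* ``theta`` -- an 8 Hz non-negative sinusoidal permeability modulation
  (awake/REM-like input), offset so its trough is zero and its
  peak-to-peak amplitude equals the configured amplitude;
* ``swr`` -- a stereotyped ~150 ms sharp-wave-ripple waveform (Gaussian
  sharp wave minus a ripple-modulated Gaussian, ripple 150 Hz) repeating
  at 3 Hz over an otherwise silent background.

Current-based probes (step, chirp) and the voltage-reset pulse used before
theta-to-SWR switches are defined here as well, so a whole experiment is an
ordered list of :class:`Epoch`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Epoch",
    "StimulusProgram",
    "theta_drive",
    "swr_waveform",
    "swr_train",
    "chirp",
    "reset_pulse",
    "preset_program",
    "calibrate_theta_amplitude",
    "calibrate_swr_amplitude",
    "CalibrationError",
    "SWR_WAVEFORM_MS",
]


class CalibrationError(RuntimeError):
    pass

EPOCH_KINDS = ("theta", "swr", "reset", "current_step", "chirp", "silent")

#: nominal support of one ripple event, ms
SWR_WAVEFORM_MS = 150.0


@dataclass(frozen=True)
class Epoch:
    kind: str
    duration: float  # ms
    amplitude: float = 0.0  # permeability (cm/s) for synaptic kinds, pA for current kinds
    frequency: float = 8.0  # Hz: theta frequency / SWR repeat rate / chirp f_max
    ripple_frequency: float = 150.0  # Hz, SWR only

    def __post_init__(self):
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.kind in ("theta", "swr", "chirp") and self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.kind == "swr" and 1e3 / self.frequency < SWR_WAVEFORM_MS:
            raise ValueError(
                "SWR repeat period shorter than the ~150 ms waveform support"
            )


@dataclass(frozen=True)
class StimulusProgram:
    epochs: tuple[Epoch, ...]
    seed: int | None = None

    def __post_init__(self):
        if not self.epochs:
            raise ValueError("a stimulus program needs at least one epoch")

    @property
    def duration(self) -> float:
        return sum(e.duration for e in self.epochs)


def theta_drive(t, amplitude: float, frequency: float = 8.0):
    """Non-negative sinusoidal permeability, peak-to-peak = amplitude.

    ``amplitude/2 * (1 - cos(2 pi f t))``: starts at zero, mean over whole
    cycles is amplitude/2.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    t = np.asarray(t, dtype=float)
    out = 0.5 * amplitude * (1.0 - np.cos(2.0 * math.pi * frequency * t / 1e3))
    return out if out.ndim else float(out)


def swr_waveform(t, ripple_frequency: float = 150.0):
    """Dimensionless SWR shape at time t (ms) from event onset.

    A broad Gaussian sharp wave centered at 55 ms minus a ripple-frequency
    sinusoid under a narrower Gaussian envelope centered at 40 ms.
    """
    t = np.asarray(t, dtype=float)
    sharp = np.exp(-((t - 55.0) ** 2) / (2.0 * 20.0 * 20.0))
    ripple = 0.3 * np.exp(-((t - 40.0) ** 2) / (2.0 * 15.0 * 15.0)) * np.sin(
        2.0 * math.pi * ripple_frequency * t / 1e3
    )
    out = sharp - ripple
    return out if out.ndim else float(out)


def swr_train(t, amplitude: float, repeat_hz: float = 3.0,
              ripple_frequency: float = 150.0):
    """Permeability of the repeating SWR drive at time t (ms).

    The waveform is tiled at ``repeat_hz`` with silence between events;
    negative excursions of the shape are clipped (permeability >= 0).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    period = 1e3 / repeat_hz
    if period < SWR_WAVEFORM_MS:
        raise ValueError("repeat period shorter than the waveform support")
    t = np.asarray(t, dtype=float)
    tm = np.mod(t, period)
    shape = np.where(tm <= SWR_WAVEFORM_MS, swr_waveform(tm, ripple_frequency), 0.0)
    out = amplitude * np.clip(shape, 0.0, None)
    return out if out.ndim else float(out)


def chirp(t, amplitude_pa: float = 50.0, f_max: float = 25.0,
          span_ms: float = 25e3):
    """Linear chirp current (pA): constant amplitude, f(t) = f_max * t/span."""
    t = np.asarray(t, dtype=float)
    phase = 2.0 * math.pi * (f_max / 1e3) * t * t / (2.0 * span_ms)
    out = amplitude_pa * np.sin(phase)
    return out if out.ndim else float(out)


def reset_pulse(duration: float = 1000.0) -> Epoch:
    """Voltage clamp to -65 mV; gates and calcium keep evolving."""
    return Epoch("reset", duration)


def _drive_probe(sim_factory, kind: str, amplitude: float, duration: float,
                 frequency: float):
    # calibration probes the frozen model held at rest, like measurements
    sim = sim_factory()
    rec = sim.run(kind, duration, amplitude=amplitude, frequency=frequency,
                  record_stride=1, use_holding=True)
    return sim, rec


def calibrate_theta_amplitude(sim_factory, *, frequency: float = 8.0,
                              probe_ms: float = 2000.0,
                              upper: float = 1e-2, rel_tol: float = 0.01):
    """Smallest theta permeability amplitude that makes the model spike.

    ``sim_factory`` builds a fresh frozen simulation (reproducible
    initial state).  Bisection on the peak-to-peak permeability: an
    amplitude "elicits spikes" when the model fires at least one action
    potential per second of drive at steady state (the trailing half of a
    ``probe_ms`` theta epoch).  Converges to 1% relative tolerance.
    """
    def spikes(amplitude):
        sim, rec = _drive_probe(sim_factory, "theta", amplitude, probe_ms, frequency)
        thr = sim.params.kinetics["spike_threshold"]
        refr = sim.params.kinetics["spike_refractory"]
        half = rec.t >= rec.t[-1] - probe_ms / 2.0
        from .engine import detect_spikes
        times, _ = detect_spikes(rec.t[half], rec.v[half], thr, refr)
        return len(times) >= probe_ms / 2.0 / 1e3  # >= 1 spike per second

    lo, hi = 0.0, upper / 1024.0
    while not spikes(hi):
        lo, hi = hi, hi * 2.0
        if hi > upper:
            raise CalibrationError(
                f"no spiking up to the amplitude bracket {upper:g} cm/s")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


def calibrate_swr_amplitude(sim_factory, *, target_mv: float = 7.5,
                            tol_mv: float = 2.5, repeat_hz: float = 3.0,
                            upper: float = 1e-2, max_iter: int = 60):
    """SWR permeability amplitude giving a ~5-10 mV subthreshold response.

    Bisection on the peak voltage deflection of a single ripple event
    toward ``target_mv`` (default 7.5 mV, accepted within +-2.5 mV).
    """
    def deflection(amplitude):
        sim, rec = _drive_probe(sim_factory, "swr", amplitude,
                                1e3 / repeat_hz, repeat_hz)
        v_rest = sim.params.kinetics["v_rest"]
        return float(np.max(np.abs(rec.v - v_rest)))

    lo, hi = 0.0, upper / 1024.0
    while deflection(hi) < target_mv:
        lo, hi = hi, hi * 2.0
        if hi > upper:
            raise CalibrationError(
                f"deflection below {target_mv} mV up to bracket {upper:g} cm/s")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d = deflection(mid)
        if abs(d - target_mv) <= tol_mv:
            return mid
        if d > target_mv:
            hi = mid
        else:
            lo = mid
    raise CalibrationError("SWR amplitude search did not converge")


def preset_program(name: str, theta_amplitude: float, swr_amplitude: float,
                   epoch_ms: float = 150e3, reset_ms: float = 1000.0,
                   theta_hz: float = 8.0, swr_repeat_hz: float = 3.0) -> StimulusProgram:
    """Named switch protocols.

    ``theta-swr-theta`` and ``swr-theta-swr`` interleave the mandated reset
    pulse before every theta -> SWR transition (depolarization-block guard);
    plain ``theta`` / ``swr`` are single epochs.
    """
    theta = Epoch("theta", epoch_ms, theta_amplitude, theta_hz)
    swr = Epoch("swr", epoch_ms, swr_amplitude, swr_repeat_hz)
    if name == "theta":
        seq = [theta]
    elif name == "swr":
        seq = [swr]
    elif name == "theta-swr-theta":
        seq = [theta, reset_pulse(reset_ms), swr, theta]
    elif name == "swr-theta-swr":
        seq = [swr, theta, reset_pulse(reset_ms), swr]
    else:
        raise ValueError(f"unknown preset {name!r}")
    return StimulusProgram(tuple(seq))
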