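"""Global sensitivity analysis: random model populations and correlations.

The procedure is sampling plus post-hoc filtering: each of the 48 sampled
parameters is drawn independently and uniformly from its testing range,
every sampled neuron is probed for the seven intrinsic measurements, and a
model is declared valid only if all seven fall inside their experimental
bounds.  Pairwise Pearson correlations among the 48 parameters of the
valid subpopulation quantify how unconstrained the underlying conductances
remain (C(48,2) = 1128 coefficients).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biophysics import PARAM_TABLE, ModelParameters
from .calcium import CalciumParams
from .engine import Simulation
from .measurements import (
    MeasurementVector,
    CA1_VALIDATION_BOUNDS,
    ValidationBounds,
    impedance_profile,
    measure_f250,
    measure_rin,
    resonance_measures,
    validate,
)
from .synapses import SynapseParams

__all__ = [
    "PopulationRun",
    "sample_population",
    "evaluate_model",
    "evaluate_and_validate",
    "pairwise_correlations",
]

PARAMETER_ORDER = tuple(PARAM_TABLE.keys())


@dataclass
class PopulationRun:
    """A sampled population with its measurements and validity flags."""

    parameter_sets: list[ModelParameters]
    measurements: list[MeasurementVector | None]
    valid: np.ndarray  # bool per model
    failures: dict[int, str] = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_models(self) -> int:
        return len(self.parameter_sets)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def parameters_frame(self) -> pd.DataFrame:
        rows = [{k: mp.values[k] for k in PARAMETER_ORDER}
                for mp in self.parameter_sets]
        df = pd.DataFrame(rows)
        df.index.name = "model"
        return df

    def measurements_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(m.as_dict() if m is not None
                        else dict.fromkeys(MeasurementVector.__dataclass_fields__, np.nan))
        df = pd.DataFrame(rows)
        df["valid"] = self.valid
        df.index.name = "model"
        return df


def sample_population(n: int, seed: int | None = None,
                      ranges: dict | None = None) -> list[ModelParameters]:
    """Draw ``n`` parameter sets uniformly from the testing ranges.

    Reproducible: the same seed yields an identical population.  Ranges
    may be overridden per symbol with (low, high) pairs in printed units.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        values = {}
        for sym, row in PARAM_TABLE.items():
            lo, hi = row.low, row.high
            if ranges and sym in ranges:
                lo, hi = ranges[sym]
            if lo >= hi:
                raise ValueError(f"malformed range for {sym!r}: [{lo}, {hi}]")
            values[sym] = rng.uniform(lo, hi) * row.scale
        mp = ModelParameters(values=values, seed=seed)
        out.append(mp)
    return out


def evaluate_model(params: ModelParameters, *, dt: float = 0.05,
                   bounds: ValidationBounds = CA1_VALIDATION_BOUNDS,
                   early_exit: bool = True,
                   calcium_params: CalciumParams | None = None,
                   synapse: SynapseParams | None = None):
    """Seven measurements + validity for one model.

    With ``early_exit`` the cheap excitability probes run first and the
    25 s chirp is skipped once the model is already invalid (the validity
    verdict is unaffected: the conjunction is already false).  Returns
    (MeasurementVector | None, valid: bool).
    """
    sim = Simulation(params, calcium_params=calcium_params, synapse=synapse, dt=dt)
    f250, _, times, peaks = measure_f250(sim, return_trace=True)
    v_ap = float(peaks[-1] - params.kinetics["v_rest"]) if len(peaks) else math.nan
    ok_f = bounds.f250[0] <= f250 <= bounds.f250[1]
    ok_v = np.isfinite(v_ap) and bounds.v_ap[0] <= v_ap <= bounds.v_ap[1]
    if early_exit and not (ok_f and ok_v):
        return MeasurementVector(f250, v_ap, math.nan, math.nan,
                                 math.nan, math.nan, math.nan), False
    r_in, rin_spiked = measure_rin(sim)
    if rin_spiked:
        r_in = math.nan
    ok_r = np.isfinite(r_in) and bounds.r_in[0] <= r_in <= bounds.r_in[1]
    if early_exit and not ok_r:
        return MeasurementVector(f250, v_ap, r_in, math.nan,
                                 math.nan, math.nan, math.nan), False
    freqs, zmag, phase, spiked = impedance_profile(sim)
    f_r, z_max, q, phi_l = resonance_measures(freqs, zmag, phase)
    if spiked:
        z_max = f_r = q = phi_l = math.nan
    mv = MeasurementVector(f250, v_ap, r_in, z_max, f_r, q, phi_l)
    valid, _ = validate(mv, bounds)
    return mv, valid


def evaluate_and_validate(population: list[ModelParameters], *,
                          bounds: ValidationBounds = CA1_VALIDATION_BOUNDS,
                          dt: float = 0.05, early_exit: bool = True,
                          seed: int | None = None,
                          progress: bool = False) -> PopulationRun:
    """Evaluate every model; integration failures mark the model invalid."""
    measurements: list[MeasurementVector | None] = []
    valid = np.zeros(len(population), dtype=bool)
    failures: dict[int, str] = {}
    iterator = enumerate(population)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(list(iterator), desc="evaluating")
    for i, mp in iterator:
        try:
            mv, ok = evaluate_model(mp, dt=dt, bounds=bounds, early_exit=early_exit)
        except Exception as exc:  # integration failure: record, continue
            measurements.append(None)
            failures[i] = str(exc)
            continue
        measurements.append(mv)
        valid[i] = ok
    return PopulationRun(list(population), measurements, valid, failures, seed)


def pairwise_correlations(parameter_table: pd.DataFrame | np.ndarray,
                          method: str = "pearson"):
    """Correlation matrix and flat coefficient list over parameter pairs.

    Input rows are models, columns the 48 parameters.  Returns
    ``(matrix, flat)`` where ``flat`` has one entry per unordered pair
    (C(48,2) = 1128 for the full table); a constant column yields NaN
    coefficients, reported as such.
    """
    df = pd.DataFrame(parameter_table)
    if len(df) < 3:
        raise ValueError("need at least 3 models for correlations")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = df.corr(method=method, min_periods=1)
    # pandas leaves the diagonal at 1 even for constant columns; restore NaN
    const = df.std(ddof=0) == 0
    for c in df.columns[const]:
        mat.loc[c, :] = np.nan
        mat.loc[:, c] = np.nan
    vals = mat.to_numpy()
    iu = np.triu_indices(len(mat), k=1)
    return mat, vals[iu]
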