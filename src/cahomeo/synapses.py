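"""GHK-based AMPAR/NMDAR synaptic currents with magnesium block.

The compartment carries one lumped glutamatergic synapse whose AMPAR and
NMDAR permeabilities are driven directly by the stimulus programs (no
receptor rise/decay kinetics on top).  Each ionic component is a
Goldman-Hodgkin-Katz flux; the NMDAR components are additionally scaled
by the voltage-dependent magnesium block and the NMDAR permeability is
tied to the AMPAR one through the NMDAR:AMPAR ratio (NAR).

Currents are densities (mA/cm2) over the compartment surface; inward is
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import FARADAY, GAS_CONSTANT, TEMPERATURE

__all__ = [
    "IonConcentrations",
    "SynapseParams",
    "ghk_current",
    "mg_block",
    "ampar_current",
    "nmdar_current",
]

#: below this |zvF/RT| the GHK expression is evaluated by Taylor expansion
_GHK_SMALL = 1e-4


@dataclass(frozen=True)
class IonConcentrations:
    """Intra/extracellular concentrations (mM) and temperature (K)."""

    na_in: float = 18.0
    na_out: float = 140.0
    k_in: float = 140.0
    k_out: float = 5.0
    ca_in: float = 50e-6
    ca_out: float = 2.0
    mg_out: float = 2.0
    temperature: float = TEMPERATURE

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        for name in ("na_in", "na_out", "k_in", "k_out", "ca_in", "ca_out", "mg_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SynapseParams:
    """Lumped synapse: AMPAR permeability, NAR, relative permeabilities."""

    p_ampar: float = 0.0  # cm/s
    nar: float = 1.5  # NMDAR:AMPAR permeability ratio
    p_ca_nmdar: float = 10.6  # P_Ca relative to P_Na = P_K = 1
    concentrations: IonConcentrations = field(default_factory=IonConcentrations)

    def __post_init__(self):
        if self.p_ampar < 0 or self.nar < 0:
            raise ValueError("p_ampar and nar must be >= 0")


def ghk_current(p: float, z: int, v: float, c_in: float, c_out: float,
                temperature: float = TEMPERATURE) -> float:
    """GHK current density (mA/cm2) for one ion.

    p in cm/s, v in mV, concentrations in mM.  The removable singularity at
    v = 0 is replaced by its analytic limit via a second-order expansion of
    u/(1 - exp(-u)) for |u| < 1e-4, u = zvF/RT.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    u = z * FARADAY * v * 1e-3 / (GAS_CONSTANT * temperature)
    # P[cm/s] * c[mM = 1e-6 mol/cm3] * z * F -> A/cm2; *1e3 -> mA/cm2
    pref = p * z * FARADAY * 1e-3
    if abs(u) < _GHK_SMALL:
        ratio = 1.0 + u / 2.0 + u * u / 12.0
        return pref * ratio * (c_in - c_out * math.exp(-u))
    return pref * u / (1.0 - math.exp(-u)) * (c_in - c_out * math.exp(-u))


def mg_block(v: float, mg_out: float = 2.0) -> float:
    """Fraction of NMDAR current surviving the Mg2+ block at voltage v."""
    if mg_out < 0:
        raise ValueError("mg_out must be >= 0")
    return 1.0 / (1.0 + mg_out * math.exp(-0.062 * v) / 3.57)


def ampar_current(v: float, p_ampar: float, params: SynapseParams) -> float:
    """AMPAR current: sum of Na+ and K+ GHK fluxes, P_Na = P_K."""
    c = params.concentrations
    i_na = ghk_current(p_ampar, 1, v, c.na_in, c.na_out, c.temperature)
    i_k = ghk_current(p_ampar, 1, v, c.k_in, c.k_out, c.temperature)
    return i_na + i_k


def nmdar_current(v: float, p_ampar: float, params: SynapseParams) -> tuple[float, float]:
    """NMDAR current and its calcium component, both Mg-blocked.

    Returns ``(total, i_ca)``; the calcium component feeds the calcium
    dynamics as a membrane calcium source alongside the VGCCs.
    """
    c = params.concentrations
    p_n = params.nar * p_ampar
    blk = mg_block(v, c.mg_out)
    i_na = ghk_current(p_n, 1, v, c.na_in, c.na_out, c.temperature)
    i_k = ghk_current(p_n, 1, v, c.k_in, c.k_out, c.temperature)
    i_ca = ghk_current(params.p_ca_nmdar * p_n, 2, v, c.ca_in, c.ca_out, c.temperature)
    return blk * (i_na + i_k + i_ca), blk * i_ca
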