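"""Cytosolic calcium dynamics: shells, buffer, SERCA, ER leak, pumps.

The cylindrical compartment is divided radially into four concentric
annuli.  The outermost (submembrane) shell is 10% of the radius thick and
carries every membrane-coupled flux: calcium entry through VGCCs and
NMDARs, SERCA uptake into the ER, the passive ER leak, and the
plasma-membrane extrusion pump.  A static buffer is present in every
shell, and calcium diffuses between adjacent shells.  The concentration of
the outer shell is "the" cytosolic calcium that the homeostasis controller
senses.

Per-shell dynamics (outer shell shown; inner shells keep only diffusion
and buffering):

    d[Ca]/dt = D_Ca * laplacian + beta*(J_leak - J_SERCA) + R_buf
               + J_VGCC - J_pump

with
    J_leak  = L * (1 - [Ca]/[Ca]_ER)
    J_SERCA = V_max * [Ca]^2 / ([Ca]^2 + K_p^2)
    J_pump  = gamma * ([Ca] - [Ca]_crt)  for [Ca] >= [Ca]_crt, else 0
    R_buf   = -k_on*[Ca]*[B] + k_off*[CaB],   K_buf = k_off/k_on

The leak constant L is calibrated so that the resting state carries no net
ER flux, making the resting concentration a fixed point of the sealed
system.  All fluxes are in mM/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .biophysics import Geometry, lateral_area
from .constants import FARADAY

__all__ = [
    "CalciumParams",
    "ShellGrid",
    "build_shells",
    "serca_uptake",
    "membrane_pump",
    "er_leak",
    "calibrate_leak",
    "buffer_rate",
    "equilibrium_bound_buffer",
    "vgcc_influx",
    "diffuse_step",
]


@dataclass(frozen=True)
class CalciumParams:
    """Calcium-handling constants (canonical units: mM, ms, um)."""

    d_ca: float = 0.22  # diffusion coefficient, um2/ms
    n_annuli: int = 4
    outer_fraction: float = 0.02  # submembrane shell: fraction of radius (1 um)
    buffer_total: float = 0.45  # mM
    k_buf: float = 0.01  # mM, dissociation constant k_off/k_on
    k_on: float = 10.0  # 1/(mM ms); fast relative to membrane dynamics
    v_max_serca: float = 1e-4  # mM/ms
    k_p: float = 2.7e-4  # mM
    gamma_pump: float = 8.0  # um/s, membrane extrusion sensitivity
    ca_crt: float = 2e-4  # mM, pump activation threshold
    ca_er: float = 0.4  # mM
    beta_er: float = 1.0  # ER leak/SERCA density factor
    resting_ca: float = 5e-5  # mM
    leak_constant: float | None = None  # mM/ms; None -> calibrated

    @property
    def k_off(self) -> float:
        return self.k_buf * self.k_on

    def resolved(self) -> "CalciumParams":
        """Copy with the ER leak constant calibrated if unset."""
        if self.leak_constant is not None:
            return self
        return replace(self, leak_constant=calibrate_leak(self))


def serca_uptake(ca: float, params: CalciumParams) -> float:
    """SERCA uptake flux V_max*ca^2/(ca^2 + K_p^2); half-maximal at K_p."""
    if ca < 0:
        raise ValueError("calcium must be >= 0")
    ca2 = ca * ca
    return params.v_max_serca * ca2 / (ca2 + params.k_p * params.k_p)


def effective_pump_rate(params: CalciumParams, geometry: Geometry) -> float:
    """Pump sensitivity as a rate constant (1/ms) on the outer shell.

    gamma is specified as a surface rate (um/s); dividing by the outer
    shell's volume-to-surface ratio converts it to a concentration rate.
    """
    grid = build_shells(geometry, params.n_annuli, params.outer_fraction)
    area_um2 = math.pi * geometry.diameter * geometry.length
    return params.gamma_pump * 1e-3 * area_um2 / grid.volumes_um3[0]


def membrane_pump(ca: float, params: CalciumParams, rate: float) -> float:
    """Plasma-membrane extrusion, threshold-linear and continuous at ca_crt.

    ``rate`` is the effective rate constant (1/ms) from
    :func:`effective_pump_rate`.
    """
    if ca < 0:
        raise ValueError("calcium must be >= 0")
    if ca <= params.ca_crt:
        return 0.0
    return rate * (ca - params.ca_crt)


def er_leak(ca: float, params: CalciumParams) -> float:
    """ER leak flux L*(1 - ca/ca_ER); influx (positive) below ca_ER."""
    if params.ca_er <= 0:
        raise ValueError("ca_er must be > 0")
    if params.leak_constant is None:
        raise ValueError("leak constant not calibrated; call resolved()")
    return params.leak_constant * (1.0 - ca / params.ca_er)


def calibrate_leak(params: CalciumParams, resting_ca: float | None = None) -> float:
    """Leak constant making ER fluxes balance at the resting concentration.

    Solves er_leak(rest) = serca_uptake(rest) for L, so the sealed system
    is stationary at rest.
    """
    rest = params.resting_ca if resting_ca is None else resting_ca
    if rest >= params.ca_er:
        raise ValueError("resting calcium must be below the ER concentration")
    uptake = serca_uptake(rest, params)
    return uptake / (1.0 - rest / params.ca_er)


def equilibrium_bound_buffer(ca: float, params: CalciumParams) -> float:
    """Bound-buffer concentration at detailed balance for free calcium ca."""
    return params.buffer_total * ca / (ca + params.k_buf)


def buffer_rate(ca: float, b_free: float, ca_b: float,
                params: CalciumParams) -> tuple[float, float]:
    """(R_buf, d[CaB]/dt) for the static buffer.

    R_buf = -k_on*ca*b_free + k_off*ca_b enters the calcium equation; the
    bound pool changes by -R_buf so that ca + ca_b is conserved.  The free
    and bound pools must sum to the total buffer concentration.
    """
    if not math.isclose(b_free + ca_b, params.buffer_total,
                        rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError("buffer conservation violated: free + bound != total")
    r = -params.k_on * ca * b_free + params.k_off * ca_b
    return r, -r


def vgcc_influx(i_ca: float, geometry: Geometry, params: CalciumParams) -> float:
    """Concentration flux (mM/ms) into the outer shell from membrane calcium
    current density ``i_ca`` (mA/cm2; inward negative -> positive flux).

    The total calcium current over the compartment surface is converted to
    a molar rate through 2F and referred to the outer-shell volume.
    """
    grid = build_shells(geometry, params.n_annuli, params.outer_fraction)
    v_litre = grid.volumes_um3[0] * 1e-15
    total_amp = i_ca * 1e-3 * lateral_area(geometry)  # A
    return -total_amp / (2.0 * FARADAY * v_litre)  # mol/(s L) == mM/ms


# -- radial shell grid -----------------------------------------------------

@dataclass(frozen=True)
class ShellGrid:
    """Precomputed annulus geometry: shell 0 is the outermost.

    ``coupling_um3`` holds D_Ca * A_interface / dr for the three interfaces
    (um3/ms), so the volume-conservative exchange between shells i and i+1
    is coupling[i] * (c[i+1] - c[i]).
    """

    boundaries_um: np.ndarray  # radii, descending, length n+1
    volumes_um3: np.ndarray  # length n
    coupling_um3: np.ndarray  # length n-1

    @property
    def n(self) -> int:
        return len(self.volumes_um3)


def build_shells(geometry: Geometry, n_annuli: int = 4,
                 outer_fraction: float = 0.1, d_ca: float = 0.22) -> ShellGrid:
    """Split the cylinder into concentric annuli.

    The submembrane shell takes ``outer_fraction`` of the radius; the
    remaining radius is divided into ``n_annuli - 1`` equal-thickness
    annuli (the innermost is a solid core cylinder).
    """
    if n_annuli < 2:
        raise ValueError("need at least 2 annuli")
    radius = geometry.radius
    inner_edge = radius * (1.0 - outer_fraction)
    bounds = [radius, inner_edge]
    step = inner_edge / (n_annuli - 1)
    for i in range(1, n_annuli - 1):
        bounds.append(inner_edge - i * step)
    bounds.append(0.0)
    b = np.array(bounds)
    vols = math.pi * (b[:-1] ** 2 - b[1:] ** 2) * geometry.length
    centers = 0.5 * (b[:-1] + b[1:])
    dr = centers[:-1] - centers[1:]
    a_int = 2.0 * math.pi * b[1:-1] * geometry.length
    coupling = d_ca * a_int / dr
    return ShellGrid(b, vols, coupling)


def diffuse_step(shells: np.ndarray, grid: ShellGrid, dt: float) -> np.ndarray:
    """One explicit radial-diffusion step; conserves volume-weighted calcium.

    Raises if dt violates the explicit-scheme stability bound.
    """
    shells = np.asarray(shells, dtype=float)
    if shells.shape != (grid.n,):
        raise ValueError(f"expected {grid.n} shells")
    lam = np.max(grid.coupling_um3 / np.minimum(grid.volumes_um3[:-1],
                                                grid.volumes_um3[1:]))
    if dt * lam > 0.5:
        raise ValueError(
            f"dt={dt} ms unstable for explicit diffusion; need dt < {0.5 / lam:.3g} ms"
        )
    flux = grid.coupling_um3 * np.diff(shells)  # um3/ms * mM
    out = shells.copy()
    out[:-1] += dt * flux / grid.volumes_um3[:-1]
    out[1:] -= dt * flux / grid.volumes_um3[1:]
    return out
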