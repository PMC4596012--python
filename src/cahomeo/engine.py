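"""Coupled integration of membrane, synapse, calcium and homeostasis.

A single compiled kernel advances the full state -- voltage, 17 gating
variables, 4 calcium shells, 4 bound-buffer pools, and optionally the 12
mRNA/conductance pairs of the homeostasis controller -- with exponential
Euler for the gates and conductance relaxation (their time constants are
voltage independent, so the per-gate update factor is exact) and forward
Euler for voltage and calcium.  Default step 0.025 ms.

The kernel is deliberately monolithic: the per-step cost is ~20
exponentials and the simulated protocols run to hundreds of seconds, so the
hot loop stays in one nopython function.  The readable, unit-tested
definitions of every flux live in :mod:`cahomeo.biophysics`,
:mod:`cahomeo.synapses` and :mod:`cahomeo.calcium`; consistency between the
two paths is asserted by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .biophysics import ModelParameters, default_conductances, lateral_area
from .calcium import (
    CalciumParams,
    build_shells,
    effective_pump_rate,
    equilibrium_bound_buffer,
)
from .constants import FARADAY, GAS_CONSTANT
from .stimulus import SWR_WAVEFORM_MS, Epoch
from .synapses import SynapseParams, ghk_current

__all__ = ["Simulation", "NeuronState", "SimRecord", "IntegrationError"]


class IntegrationError(RuntimeError):
    pass


# gate indices
G_NA_M, G_NA_H, G_NA_S = 0, 1, 2
G_DR_N = 3
G_A_N, G_A_L = 4, 5
G_KM = 6
G_HCN = 7
G_T_M, G_T_H = 8, 9
G_R_M, G_R_H = 10, 11
G_N_M, G_N_H = 12, 13
G_L_M = 14
G_SK, G_BK = 15, 16
N_GATES = 17

# drive kinds
DRIVE_SILENT, DRIVE_THETA, DRIVE_SWR, DRIVE_STEP, DRIVE_CHIRP, DRIVE_CLAMP = range(6)

STATUS_OK, STATUS_NONFINITE, STATUS_WINDUP = 0, 1, 2


@njit(cache=True)
def _ipow(x, n):
    out = x
    for _ in range(n - 1):
        out *= x
    return out


@njit(cache=True)
def _ghk(p, z, v, c_in, c_out, temperature):
    u = z * FARADAY * v * 1e-3 / (GAS_CONSTANT * temperature)
    pref = p * z * FARADAY * 1e-3
    if abs(u) < 1e-4:
        ratio = 1.0 + u * 0.5 + u * u / 12.0
        return pref * ratio * (c_in - c_out * math.exp(-u))
    return pref * u / (1.0 - math.exp(-u)) * (c_in - c_out * math.exp(-u))


@njit(cache=True)
def _run(state, gb, galpha, gexp, skbk, g12, mem, syn, cap, dcoef, vols,
         drive, hom_on, m12, tau_i, tau_g, ca_tgt, g_ceiling,
         t0, n_steps, dt, rec_stride, out_t, out_v, out_ca, out_i,
         g_stride, out_g, out_m):
    v = state[0]
    gates = state[1:1 + N_GATES]
    ca = state[18:22]
    cab = state[22:26]

    c_m = mem[0]
    area = mem[1]
    e_na, e_k, e_h, e_ca, e_leak = mem[2], mem[3], mem[4], mem[5], mem[6]
    kappa = mem[7]

    nar = syn[0]
    na_i, na_o = syn[1], syn[2]
    k_i, k_o = syn[3], syn[4]
    cai, cao = syn[5], syn[6]
    mg_o, temp, pca = syn[7], syn[8], syn[9]

    btot, kon, koff = cap[0], cap[1], cap[2]
    vmax, kp = cap[3], cap[4]
    gamma_eff, ca_crt, ca_er = cap[5], cap[6], cap[7]
    beta, lleak, i2flux = cap[8], cap[9], cap[10]

    kind = int(drive[0])
    amp, p1, p2, hold_pa = drive[1], drive[2], drive[3], drive[4]

    ag = 1.0 - math.exp(-dt / tau_g) if hom_on == 1 else 0.0
    kp2 = kp * kp

    status = STATUS_OK
    for istep in range(n_steps):
        t = t0 + istep * dt

        # ---- drive -------------------------------------------------------
        p_a = 0.0
        i_inj = hold_pa
        if kind == DRIVE_THETA:
            p_a = 0.5 * amp * (1.0 - math.cos(2.0e-3 * math.pi * p1 * t))
        elif kind == DRIVE_SWR:
            tm = t % p1
            if tm <= SWR_WAVEFORM_MS:
                s = math.exp(-((tm - 55.0) ** 2) / 800.0) \
                    - 0.3 * math.exp(-((tm - 40.0) ** 2) / 450.0) \
                    * math.sin(2.0e-3 * math.pi * p2 * tm)
                if s > 0.0:
                    p_a = amp * s
        elif kind == DRIVE_STEP:
            i_inj = hold_pa + amp
        elif kind == DRIVE_CHIRP:
            phase = 2.0 * math.pi * (p1 * 1e-3) * t * t / (2.0 * p2)
            i_inj = hold_pa + amp * math.sin(phase)

        # ---- membrane currents (mA/cm2) ---------------------------------
        ca0 = ca[0]
        i_leak = g12[0] * (v - e_leak)
        i_na = g12[1] * _ipow(gates[G_NA_M], gexp[G_NA_M]) \
            * _ipow(gates[G_NA_H], gexp[G_NA_H]) \
            * _ipow(gates[G_NA_S], gexp[G_NA_S]) * (v - e_na)
        i_dr = g12[2] * _ipow(gates[G_DR_N], gexp[G_DR_N]) * (v - e_k)
        i_a = g12[3] * _ipow(gates[G_A_N], gexp[G_A_N]) \
            * _ipow(gates[G_A_L], gexp[G_A_L]) * (v - e_k)
        i_m = g12[4] * gates[G_KM] * (v - e_k)
        i_h = g12[5] * gates[G_HCN] * (v - e_h)
        # Ca channels: GHK driving force in mV (rectifying); kappa == 0
        # selects the plain ohmic driving toward the nominal E_Ca instead
        if kappa != 0.0:
            cadrv = kappa * _ghk(1.0, 2, v, ca0, cao, temp)
        else:
            cadrv = v - e_ca
        i_cat = g12[6] * _ipow(gates[G_T_M], gexp[G_T_M]) * gates[G_T_H] * cadrv
        i_car = g12[7] * _ipow(gates[G_R_M], gexp[G_R_M]) * gates[G_R_H] * cadrv
        i_can = g12[8] * _ipow(gates[G_N_M], gexp[G_N_M]) * gates[G_N_H] * cadrv
        i_cal = g12[9] * _ipow(gates[G_L_M], gexp[G_L_M]) * cadrv
        i_sk = g12[10] * gates[G_SK] * (v - e_k)
        i_bk = g12[11] * gates[G_BK] * (v - e_k)

        i_syn = 0.0
        i_syn_ca = 0.0
        if p_a > 0.0:
            i_ampar = _ghk(p_a, 1, v, na_i, na_o, temp) \
                + _ghk(p_a, 1, v, k_i, k_o, temp)
            p_n = nar * p_a
            blk = 1.0 / (1.0 + mg_o * math.exp(-0.062 * v) / 3.57)
            i_nm = _ghk(p_n, 1, v, na_i, na_o, temp) \
                + _ghk(p_n, 1, v, k_i, k_o, temp)
            i_nm_ca = _ghk(pca * p_n, 2, v, cai, cao, temp)
            i_syn = i_ampar + blk * (i_nm + i_nm_ca)
            i_syn_ca = blk * i_nm_ca

        i_ion = (i_leak + i_na + i_dr + i_a + i_m + i_h
                 + i_cat + i_car + i_can + i_cal + i_sk + i_bk)
        i_ca_total = i_cat + i_car + i_can + i_cal + i_syn_ca

        # ---- voltage -----------------------------------------------------
        if kind == DRIVE_CLAMP:
            v = p1
        else:
            i_net = -(i_ion + i_syn) + i_inj * 1e-9 / area
            v = v + dt * 1e3 * i_net / c_m
            if not math.isfinite(v):
                status = STATUS_NONFINITE
                break

        # ---- gates (exponential Euler; tau constant) --------------------
        for j in range(15):
            xinf = 1.0 / (1.0 + math.exp(-(v - gb[j, 0]) / gb[j, 1]))
            gates[j] += (xinf - gates[j]) * galpha[j]
        # SK: Hill in calcium
        r = (ca0 / skbk[0]) ** skbk[1]
        gates[G_SK] += (r / (1.0 + r) - gates[G_SK]) * galpha[G_SK]
        # BK: Moczydlowski-Latorre steady state, fixed tau
        vfrt = FARADAY * v * 1e-3 / (GAS_CONSTANT * temp)
        k1e = skbk[2] * math.exp(-2.0 * skbk[4] * vfrt)
        k2e = skbk[3] * math.exp(-2.0 * skbk[5] * vfrt)
        al = skbk[6] * ca0 / (ca0 + k1e)
        be = skbk[7] / (1.0 + ca0 / k2e)
        gates[G_BK] += (al / (al + be) - gates[G_BK]) * galpha[G_BK]

        # ---- calcium shells ---------------------------------------------
        f0 = dcoef[0] * (ca[1] - ca[0])
        f1 = dcoef[1] * (ca[2] - ca[1])
        f2 = dcoef[2] * (ca[3] - ca[2])
        d0 = f0 / vols[0]
        d1 = (f1 - f0) / vols[1]
        d2 = (f2 - f1) / vols[2]
        d3 = -f2 / vols[3]

        # outer shell sources
        j_in = -i_ca_total * i2flux
        j_serca = vmax * ca0 * ca0 / (ca0 * ca0 + kp2)
        j_leak_er = lleak * (1.0 - ca0 / ca_er)
        j_pump = gamma_eff * (ca0 - ca_crt) if ca0 > ca_crt else 0.0
        d0 += j_in + beta * (j_leak_er - j_serca) - j_pump

        for j in range(4):
            rb = -kon * ca[j] * (btot - cab[j]) + koff * cab[j]
            dca = d0 if j == 0 else (d1 if j == 1 else (d2 if j == 2 else d3))
            ca[j] += dt * (dca + rb)
            cab[j] -= dt * rb
            if ca[j] < 0.0:
                ca[j] = 0.0

        # ---- homeostasis -------------------------------------------------
        if hom_on == 1:
            err = ca_tgt - ca[0]
            for j in range(12):
                m12[j] += dt * err / tau_i[j]
                if m12[j] < 0.0:
                    m12[j] = 0.0
                g12[j] += (m12[j] - g12[j]) * ag
                if g12[j] < 0.0:
                    g12[j] = 0.0
                if g12[j] > g_ceiling[j]:
                    status = STATUS_WINDUP
            if status != STATUS_OK:
                break

        # ---- record ------------------------------------------------------
        if (istep + 1) % rec_stride == 0:
            ri = (istep + 1) // rec_stride - 1
            out_t[ri] = t + dt
            out_v[ri] = v
            out_ca[ri] = ca[0]
            out_i[ri] = i_inj
        if g_stride > 0 and (istep + 1) % g_stride == 0:
            gi = (istep + 1) // g_stride - 1
            for j in range(12):
                out_g[gi, j] = g12[j]
                out_m[gi, j] = m12[j]

    state[0] = v
    return status


@dataclass
class NeuronState:
    """Full integrator state; ``gates`` follow the engine's gate indices."""

    voltage: float
    gates: np.ndarray  # (17,)
    calcium_shells: np.ndarray  # (4,) mM, outermost first
    buffer_bound: np.ndarray  # (4,) mM
    time: float = 0.0

    def pack(self) -> np.ndarray:
        out = np.empty(26)
        out[0] = self.voltage
        out[1:18] = self.gates
        out[18:22] = self.calcium_shells
        out[22:26] = self.buffer_bound
        return out

    @classmethod
    def unpack(cls, arr: np.ndarray, time: float) -> "NeuronState":
        return cls(float(arr[0]), arr[1:18].copy(), arr[18:22].copy(),
                   arr[22:26].copy(), time)

    def copy(self) -> "NeuronState":
        return NeuronState(self.voltage, self.gates.copy(),
                           self.calcium_shells.copy(), self.buffer_bound.copy(),
                           self.time)


@dataclass
class SimRecord:
    """Recorded trajectory of one epoch (times in ms)."""

    t: np.ndarray
    v: np.ndarray
    ca: np.ndarray  # outer-shell calcium, mM
    i_inj: np.ndarray  # injected current, pA
    g: np.ndarray | None = None  # (n, 12) conductance trajectory
    m: np.ndarray | None = None  # (n, 12) mRNA trajectory


def _gate_tables(params: ModelParameters):
    """(vhalf, slope) table for the 15 voltage gates + tau for all 17."""
    v, k = params.values, params.kinetics
    gb = np.array([
        [v["Na-V_m"], k["k-Na_m"]],
        [v["Na-V_h"], k["k-Na_h"]],
        [v["Na-V_s"], k["k-Na_s"]],
        [v["DR-V_n"], k["k-DR_n"]],
        [v["A-V_n"], k["k-A_n"]],
        [v["A-V_l"], k["k-A_l"]],
        [v["M-V"], k["k-M"]],
        [v["h-V_l"], k["k-h"]],
        [v["T-V_m"], k["k-T_m"]],
        [v["T-V_h"], k["k-T_h"]],
        [v["R-V_m"], k["k-R_m"]],
        [v["R-V_h"], k["k-R_h"]],
        [v["N-V_m"], k["k-N_m"]],
        [v["N-V_h"], k["k-N_h"]],
        [v["L-V_a"], k["k-L_m"]],
    ])
    tau = np.array([
        v["Na-tau_m"], v["Na-tau_h"], v["Na-tau_s"],
        v["DR-tau_n"],
        v["A-tau_n"], v["A-tau_l"],
        v["M-tau"],
        v["h-tau_l"],
        v["T-tau_m"], v["T-tau_h"],
        v["R-tau_m"], v["R-tau_h"],
        v["N-tau_m"], v["N-tau_h"],
        v["L-tau_m"],
        v["SK-tau"], v["BK-tau"],
    ])
    return gb, tau


class Simulation:
    """One neuron plus its calcium handling and synapse, ready to integrate.

    Conductances live in ``self.g12`` (canonical roster order) and may be
    evolved in place by the homeostasis controller; the sampled kinetic
    parameters stay fixed.
    """

    def __init__(self, params: ModelParameters,
                 calcium_params: CalciumParams | None = None,
                 synapse: SynapseParams | None = None,
                 dt: float = 0.025):
        if dt <= 0:
            raise ValueError("dt must be > 0")
        self.params = params
        self.capar = (calcium_params or CalciumParams()).resolved()
        self.synapse = synapse or SynapseParams()
        self.dt = dt
        self.g12 = default_conductances(params)

        self._gb, self._tau = _gate_tables(params)
        k = params.kinetics
        self._gexp = np.array([
            int(k.get("exp-Na_m", 3)), int(k.get("exp-Na_h", 1)),
            int(k.get("exp-Na_s", 1)), int(k.get("exp-DR_n", 1)),
            int(k.get("exp-A_n", 1)), int(k.get("exp-A_l", 1)),
            1, 1,
            int(k.get("exp-T_m", 2)), 1,
            int(k.get("exp-R_m", 3)), 1,
            int(k.get("exp-N_m", 2)), 1,
            int(k.get("exp-L_m", 1)),
        ], dtype=np.int64)
        self._skbk = np.array([
            params.values["SK-Ca"], k["SK-hill"],
            params.values["BK-k_1"], params.values["BK-k_2"],
            k["BK-d1"], k["BK-d2"], k["BK-abar"], k["BK-bbar"],
        ])
        area = lateral_area(params.geometry)
        c = self.synapse.concentrations
        # Ca-channel driving: by default the canonical GHK driving force in
        # mV, D(v) = kappa * GHK_flux(P=1, z=2, v, ca_i, ca_o), with
        # kappa = (RT/2F) / (2 F ca_o * 1e-3); at rest this is ~ -66 mV and
        # it rectifies toward zero at depolarized potentials.  Setting the
        # kinetic option ca-driving-ohmic selects g*(v - E_Ca) instead.
        if k.get("ca-driving-ohmic", 0.0):
            kappa = 0.0
        else:
            x_mv = 1e3 * GAS_CONSTANT * c.temperature / (2.0 * FARADAY)
            kappa = x_mv / (2.0 * FARADAY * 1e-3 * c.ca_out)
        self._mem = np.array([
            params.values["C_m"], area,
            k["E_Na"], k["E_K"], k["E_h"], k["E_Ca"], k["E_leak"], kappa,
        ])
        self._syn = np.array([
            self.synapse.nar, c.na_in, c.na_out, c.k_in, c.k_out,
            c.ca_in, c.ca_out, c.mg_out, c.temperature, self.synapse.p_ca_nmdar,
        ])
        cp = self.capar
        grid = build_shells(params.geometry, cp.n_annuli, cp.outer_fraction,
                            d_ca=cp.d_ca)
        self._grid = grid
        v_outer_l = grid.volumes_um3[0] * 1e-15
        i2flux = 1e-3 * area / (2.0 * FARADAY * v_outer_l)
        self._cap = np.array([
            cp.buffer_total, cp.k_on, cp.k_off, cp.v_max_serca, cp.k_p,
            effective_pump_rate(cp, params.geometry), cp.ca_crt, cp.ca_er,
            cp.beta_er, cp.leak_constant, i2flux,
        ])
        self._dcoef = grid.coupling_um3
        self._vols = grid.volumes_um3

        self.state = self.rest_state()
        self.hold_pa = self.holding_current()

    # -- initialization ----------------------------------------------------

    def rest_state(self, v: float | None = None) -> NeuronState:
        """State with gates at steady state for v, calcium at rest."""
        v = self.params.kinetics["v_rest"] if v is None else v
        cp = self.capar
        gates = np.empty(N_GATES)
        gates[:15] = 1.0 / (1.0 + np.exp(-(v - self._gb[:, 0]) / self._gb[:, 1]))
        ca0 = cp.resting_ca
        r = (ca0 / self._skbk[0]) ** self._skbk[1]
        gates[G_SK] = r / (1.0 + r)
        vfrt = FARADAY * v * 1e-3 / (GAS_CONSTANT * self._syn[8])
        k1e = self._skbk[2] * math.exp(-2.0 * self._skbk[4] * vfrt)
        k2e = self._skbk[3] * math.exp(-2.0 * self._skbk[5] * vfrt)
        al = self._skbk[6] * ca0 / (ca0 + k1e)
        be = self._skbk[7] / (1.0 + ca0 / k2e)
        gates[G_BK] = al / (al + be)
        ca = np.full(4, ca0)
        cab = np.full(4, equilibrium_bound_buffer(ca0, cp))
        return NeuronState(v, gates, ca, cab, 0.0)

    def membrane_current(self, state: NeuronState | None = None) -> float:
        """Total ionic current density (mA/cm2) at a state, no synapse."""
        s = state or self.state
        g = self.g12
        gates = s.gates.copy()
        gates[:15] = s.gates[:15] ** self._gexp
        v = s.voltage
        e = self._mem
        i = g[0] * (v - e[6])
        i += g[1] * gates[G_NA_M] * gates[G_NA_H] * gates[G_NA_S] * (v - e[2])
        i += (g[2] * gates[G_DR_N] + g[3] * gates[G_A_N] * gates[G_A_L]
              + g[4] * gates[G_KM] + g[10] * gates[G_SK]
              + g[11] * gates[G_BK]) * (v - e[3])
        i += g[5] * gates[G_HCN] * (v - e[4])
        if e[7] != 0.0:
            cadrv = e[7] * ghk_current(1.0, 2, v, s.calcium_shells[0],
                                       self._syn[6], self._syn[8])
        else:
            cadrv = v - e[5]
        i += (g[6] * gates[G_T_M] * gates[G_T_H]
              + g[7] * gates[G_R_M] * gates[G_R_H]
              + g[8] * gates[G_N_M] * gates[G_N_H]
              + g[9] * gates[G_L_M]) * cadrv
        return i

    def holding_current(self, state: NeuronState | None = None) -> float:
        """Holding current (pA) pinning the state's voltage as rest."""
        return self.membrane_current(state) * self._mem[1] * 1e9

    # -- integration -------------------------------------------------------

    def run(self, kind: str, duration: float, *, amplitude: float = 0.0,
            frequency: float = 8.0, ripple_frequency: float = 150.0,
            f_max: float = 25.0, span_ms: float | None = None,
            clamp_mv: float | None = None,
            record_stride: int | None = None, use_holding: bool | None = None,
            homeostasis=None, g_record_ms: float = 0.0) -> SimRecord:
        """Integrate one epoch, advancing ``self.state`` (and ``self.g12``).

        ``kind`` is one of silent/theta/swr/current_step/chirp/reset.
        ``homeostasis`` is an optional
        :class:`cahomeo.homeostasis.HomeostasisEngine` evolved jointly.
        """
        dt = self.dt
        n_steps = int(round(duration / dt))
        if n_steps < 1:
            raise ValueError("duration shorter than one step")
        kmap = {"silent": DRIVE_SILENT, "theta": DRIVE_THETA, "swr": DRIVE_SWR,
                "current_step": DRIVE_STEP, "chirp": DRIVE_CHIRP,
                "reset": DRIVE_CLAMP}
        if kind not in kmap:
            raise ValueError(f"unknown drive kind {kind!r}")
        code = kmap[kind]
        if code == DRIVE_THETA:
            p1, p2 = frequency, 0.0
        elif code == DRIVE_SWR:
            p1, p2 = 1e3 / frequency, ripple_frequency
            if p1 < SWR_WAVEFORM_MS:
                raise ValueError("SWR repeat period below waveform support")
        elif code == DRIVE_CHIRP:
            p1 = f_max
            p2 = span_ms if span_ms is not None else duration
        elif code == DRIVE_CLAMP:
            p1 = self.params.kinetics["v_rest"] if clamp_mv is None else clamp_mv
            p2 = 0.0
        else:
            p1 = p2 = 0.0
        # probes run under the holding current that pins rest at -65 mV;
        # synaptic-drive epochs are unheld (the drive itself sets the regime)
        if use_holding is None:
            use_holding = code in (DRIVE_SILENT, DRIVE_STEP, DRIVE_CHIRP)
        drive = np.array([code, amplitude, p1, p2,
                          self.hold_pa if use_holding else 0.0])

        if record_stride is None:
            record_stride = max(1, int(round(0.1 / dt)))  # 0.1 ms default
        n_rec = n_steps // record_stride
        out_t = np.empty(n_rec)
        out_v = np.empty(n_rec)
        out_ca = np.empty(n_rec)
        out_i = np.empty(n_rec)

        galpha = 1.0 - np.exp(-dt / self._tau)

        if homeostasis is not None:
            hom_on = 1
            m12 = homeostasis.mrna
            tau_i = homeostasis.tau_mrna
            tau_g = homeostasis.tau_translation
            ca_tgt = homeostasis.ca_target
            g_ceiling = homeostasis.g_ceiling
        else:
            hom_on = 0
            m12 = np.zeros(12)
            tau_i = np.ones(12)
            tau_g = 1.0
            ca_tgt = 0.0
            g_ceiling = np.full(12, np.inf)

        if g_record_ms > 0:
            g_stride = max(1, int(round(g_record_ms / dt)))
            n_g = n_steps // g_stride
            out_g = np.empty((n_g, 12))
            out_m = np.empty((n_g, 12))
        else:
            g_stride = 0
            out_g = np.empty((0, 12))
            out_m = np.empty((0, 12))

        arr = self.state.pack()
        status = _run(arr, self._gb, galpha, self._gexp, self._skbk, self.g12, self._mem,
                      self._syn, self._cap, self._dcoef, self._vols, drive,
                      hom_on, m12, tau_i, tau_g, ca_tgt, g_ceiling,
                      self.state.time, n_steps, dt, record_stride,
                      out_t, out_v, out_ca, out_i, g_stride, out_g, out_m)
        if status == STATUS_NONFINITE:
            raise IntegrationError(
                f"non-finite membrane voltage during {kind!r} epoch"
            )
        if status == STATUS_WINDUP:
            raise IntegrationError(
                "homeostatic windup: a conductance exceeded its safety ceiling"
            )
        self.state = NeuronState.unpack(arr, self.state.time + n_steps * dt)
        return SimRecord(out_t, out_v, out_ca, out_i,
                         out_g if g_stride else None,
                         out_m if g_stride else None)

    def run_epoch(self, epoch: Epoch, **kwargs) -> SimRecord:
        if epoch.kind == "theta":
            return self.run("theta", epoch.duration, amplitude=epoch.amplitude,
                            frequency=epoch.frequency, **kwargs)
        if epoch.kind == "swr":
            return self.run("swr", epoch.duration, amplitude=epoch.amplitude,
                            frequency=epoch.frequency,
                            ripple_frequency=epoch.ripple_frequency, **kwargs)
        if epoch.kind == "reset":
            return self.run("reset", epoch.duration, **kwargs)
        if epoch.kind == "current_step":
            return self.run("current_step", epoch.duration,
                            amplitude=epoch.amplitude, **kwargs)
        if epoch.kind == "chirp":
            return self.run("chirp", epoch.duration, amplitude=epoch.amplitude,
                            f_max=epoch.frequency, **kwargs)
        return self.run("silent", epoch.duration, **kwargs)


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = -20.0,
                  refractory: float = 2.0):
    """Spike times and peak voltages from a trace.

    A spike is an upward threshold crossing; crossings within the
    refractory window of the previous spike are ignored.  The peak is the
    maximum voltage between the crossing and the return below threshold.
    """
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times, peaks = [], []
    last = -np.inf
    for idx in crossings:
        if t[idx] - last < refractory:
            continue
        last = t[idx]
        end = idx
        while end < len(v) and v[end] >= threshold:
            end += 1
        seg = v[idx:max(end, idx + 1)]
        times.append(t[idx])
        peaks.append(float(np.max(seg)))
    return np.array(times), np.array(peaks)
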