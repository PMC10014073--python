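"""Cable-equation integrator with HH channels and intracellular Na+ diffusion.

The membrane potential is advanced by a semi-implicit (Crank-Nicolson-style)
scheme: at every time step the ionic conductances are frozen at the current
gating state, making the membrane equation linear in V, and the resulting
tree-structured linear system is solved directly by Hines elimination
(O(n) per step, parent-before-child compartment ordering).  Gating variables
are advanced by exact exponential (Rush-Larsen) integration.  Intracellular
[Na+] follows channel influx plus explicit axial diffusion between adjacent
compartments (diffusion coefficient D, default 0.6 um^2/ms) with sealed ends.

The default time step is 1 us.  The resting potential is imposed by solving
the per-compartment leak reversal so that the total membrane current vanishes
at V_rest in every compartment; with gating initialized at steady state the
initial condition is then an exact fixed point of the dynamics.

E_Na is fixed by default at the Nernst potential of the resting Na+ pools
(4 / 151 mmol/l, ~= +91 mV at 18 degC); a dynamic-Nernst mode recomputes it
from the evolving [Na+]_i.  E_K is -85 mV.

The somatic voltage clamp is ideal: the command potential is imposed on all
soma compartments (penalty rows in the linear solve) and the clamp current is
read off as the residual of the unconstrained membrane equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .model import (
    REGIONS,
    ChannelLayout,
    CompartmentGraph,
    GatingModel,
    nernst,
    steady_state_gate,
    FARADAY,
)
from .traces import Channel, TraceSet

__all__ = [
    "Protocol",
    "SimulationState",
    "CableSim",
    "initialize_state",
    "step",
    "update_sodium",
    "run_current_clamp",
    "run_voltage_ramp",
    "run_propagation_protocol",
    "SimulationError",
]

D_NA_DEFAULT = 0.6  # um^2/ms
NA_I_REST = 4.0  # mmol/l
NA_O_REST = 151.0  # mmol/l
E_K = -85.0  # mV
V_REST_DEFAULT = -75.0  # mV
DT_DEFAULT = 1e-3  # ms (1 us)
TEMPERATURE_C = 18.0

#: mM change per (nA * ms) in 1 um^3: 1e6 / F
_NA_CONV = 1e6 / FARADAY

#: regional aggregates reported as fluorescence (Delta[Na]) proxies
NA_GROUPS = ("soma", "ais", "dendrite", "axon")
_GROUP_OF_REGION = {
    "soma": 0,
    "ais_proximal": 1,
    "ais_middle": 1,
    "ais_distal": 1,
    "apical": 2,
    "basal": 2,
    "internode": 3,
    "node": 3,
}


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """A stimulation protocol.

    kind 'current_step' / 'brief_pulse_train': somatic (or other-site) current
    injection; 'voltage_ramp': ideal somatic voltage clamp ramp; 'synaptic':
    dual-exponential conductance at a dendritic site.
    """

    kind: str
    site: tuple[str, float] | int = ("soma", 0.0)
    amplitude: float = 0.0  # nA (current kinds) or nS (synaptic gmax)
    t_start: float = 1.0  # ms
    duration: float = 400.0  # ms
    n_pulses: int = 1
    interval: float = 10.0  # ms between pulses in a train
    v_start: float = -70.0  # mV (ramp)
    v_end: float = 0.0  # mV (ramp)
    tau_rise: float = 0.5  # ms (synaptic)
    tau_decay: float = 5.0  # ms (synaptic)
    e_rev: float = 0.0  # mV (synaptic)

    def __post_init__(self):
        if self.kind not in ("current_step", "brief_pulse_train", "voltage_ramp", "synaptic"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "voltage_ramp" and self.v_end <= self.v_start:
            raise ValueError("ramp must be depolarizing (v_end > v_start)")

    @classmethod
    def current_step(cls, amplitude, duration=400.0, t_start=10.0, site=("soma", 0.0)):
        return cls("current_step", site=site, amplitude=amplitude,
                   duration=duration, t_start=t_start)

    @classmethod
    def brief_pulse(cls, amplitude, duration=2.0, t_start=1.0, site=("soma", 0.0)):
        return cls("brief_pulse_train", site=site, amplitude=amplitude,
                   duration=duration, t_start=t_start)

    @classmethod
    def voltage_ramp(cls, v_start=-70.0, v_end=0.0, duration=2000.0, t_start=10.0):
        return cls("voltage_ramp", v_start=v_start, v_end=v_end,
                   duration=duration, t_start=t_start)

    @classmethod
    def synaptic(cls, gmax_nS, site=("apical", 100.0), tau_rise=0.5, tau_decay=5.0,
                 e_rev=0.0, t_start=5.0):
        return cls("synaptic", site=site, amplitude=gmax_nS, tau_rise=tau_rise,
                   tau_decay=tau_decay, e_rev=e_rev, t_start=t_start, duration=1.0)


@dataclass
class SimulationState:
    """Per-compartment dynamical variables."""

    v: np.ndarray  # mV
    m12: np.ndarray
    h12: np.ndarray
    m16: np.ndarray
    h16: np.ndarray
    nk: np.ndarray
    nk1: np.ndarray
    nai: np.ndarray  # mM
    t: float = 0.0

    def copy(self) -> "SimulationState":
        return SimulationState(
            *(a.copy() for a in (self.v, self.m12, self.h12, self.m16,
                                 self.h16, self.nk, self.nk1, self.nai)),
            t=self.t,
        )


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _boltz(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / k))


@njit(cache=True, inline="always")
def _bell(v, base, amp, vmid, width):
    u = (v - vmid) / width
    return base + amp / (np.exp(u) + np.exp(-u))


@njit(cache=True)
def _integrate(
    v, m12, h12, m16, h16, nk, nk1, nai,
    parent, gax, gax_sum, cap, vol, acoef,
    g12, g16, gkv, gkv1, gleak, eleak,
    pna12, pna16, pkv, pkv1, tau_scale,
    ena_fixed, ek, dyn_ena, nao, rtf, d_na,
    stim_comp, stim_amp, stim_t0, stim_t1,
    syn_comp, syn_gmax, syn_t0, syn_taur, syn_taud, syn_norm, syn_e,
    clamp_comp, clamp_childrow, vc_par,
    t_start, dt, nsteps, rec_every,
    rec_idx, vout, group_id, gvol, naout, iclamp_out, acc,
):
    n = v.shape[0]
    a = np.empty(n)
    rhs = np.empty(n)
    off = np.empty(n)
    vnew = np.empty(n)
    gna = np.empty(n)
    ena = np.empty(n)
    dam = np.empty(n)
    nclamp = clamp_comp.shape[0]
    a0 = np.empty(nclamp)
    r0 = np.empty(nclamp)
    csum = np.empty(nclamp)
    BIG = 1e10

    m12exp = int(pna12[13])
    m16exp = int(pna16[13])
    kvexp = int(pkv[6])
    kv1exp = int(pkv1[6])
    p12 = pna12[12]
    p16 = pna16[12]

    # row 0: initial condition
    for j in range(rec_idx.shape[0]):
        vout[0, j] = v[rec_idx[j]]
    for g in range(gvol.shape[0]):
        naout[0, g] = 0.0
    for i in range(n):
        if group_id[i] >= 0:
            naout[0, group_id[i]] += nai[i] * vol[i]
    for g in range(gvol.shape[0]):
        naout[0, g] /= gvol[g]
    iclamp_out[0] = 0.0

    row = 1
    iclamp = 0.0
    for s in range(nsteps):
        t = t_start + s * dt
        tmid = t + 0.5 * dt
        tnext = t + dt

        # --- gating: Rush-Larsen exact exponential update ---
        for i in range(n):
            vi = v[i]
            if g12[i] > 0.0:
                tm = _bell(vi, pna12[2], pna12[3], pna12[4], pna12[5]) * tau_scale
                m12[i] += (_boltz(vi, pna12[0], pna12[1]) - m12[i]) * (
                    1.0 - np.exp(-dt / tm))
                th = _bell(vi, pna12[8], pna12[9], pna12[10], pna12[11]) * tau_scale
                h12[i] += (_boltz(vi, pna12[6], pna12[7]) - h12[i]) * (
                    1.0 - np.exp(-dt / th))
            if g16[i] > 0.0:
                tm = _bell(vi, pna16[2], pna16[3], pna16[4], pna16[5]) * tau_scale
                m16[i] += (_boltz(vi, pna16[0], pna16[1]) - m16[i]) * (
                    1.0 - np.exp(-dt / tm))
                th = _bell(vi, pna16[8], pna16[9], pna16[10], pna16[11]) * tau_scale
                h16[i] += (_boltz(vi, pna16[6], pna16[7]) - h16[i]) * (
                    1.0 - np.exp(-dt / th))
            if gkv[i] > 0.0:
                tn = _bell(vi, pkv[2], pkv[3], pkv[4], pkv[5]) * tau_scale
                nk[i] += (_boltz(vi, pkv[0], pkv[1]) - nk[i]) * (
                    1.0 - np.exp(-dt / tn))
            if gkv1[i] > 0.0:
                tn = _bell(vi, pkv1[2], pkv1[3], pkv1[4], pkv1[5]) * tau_scale
                nk1[i] += (_boltz(vi, pkv1[0], pkv1[1]) - nk1[i]) * (
                    1.0 - np.exp(-dt / tn))

        # --- assemble linear system (CN in V) ---
        for i in range(n):
            vi = v[i]
            if dyn_ena:
                ena[i] = rtf * np.log(nao / nai[i])
            else:
                ena[i] = ena_fixed
            gna_i = 0.0
            if g12[i] > 0.0:
                gna_i += g12[i] * m12[i] ** m12exp * (p12 + (1.0 - p12) * h12[i])
            if g16[i] > 0.0:
                gna_i += g16[i] * m16[i] ** m16exp * (p16 + (1.0 - p16) * h16[i])
            gna[i] = gna_i
            gk_i = 0.0
            if gkv[i] > 0.0:
                gk_i += gkv[i] * nk[i] ** kvexp
            if gkv1[i] > 0.0:
                gk_i += gkv1[i] * nk1[i] ** kv1exp
            gtot = gna_i + gk_i + gleak[i]
            ge = gna_i * ena[i] + gk_i * ek + gleak[i] * eleak[i]
            a[i] = cap[i] / dt + 0.5 * (gtot + gax_sum[i])
            rhs[i] = (cap[i] / dt - 0.5 * (gtot + gax_sum[i])) * vi + ge
            off[i] = -0.5 * gax[i]
        for i in range(1, n):
            p = parent[i]
            rhs[i] += 0.5 * gax[i] * v[p]
            rhs[p] += 0.5 * gax[i] * v[i]

        # --- stimuli ---
        for j in range(stim_comp.shape[0]):
            if stim_t0[j] <= tmid < stim_t1[j]:
                rhs[stim_comp[j]] += stim_amp[j]
        for j in range(syn_comp.shape[0]):
            if tmid > syn_t0[j]:
                u = tmid - syn_t0[j]
                gs = syn_gmax[j] * syn_norm[j] * (
                    np.exp(-u / syn_taud[j]) - np.exp(-u / syn_taur[j]))
                i = syn_comp[j]
                a[i] += 0.5 * gs
                rhs[i] += gs * syn_e[j] - 0.5 * gs * v[i]

        # --- voltage clamp: penalty rows ---
        if nclamp > 0:
            if tnext <= vc_par[0]:
                vcmd = vc_par[2]
            elif tnext >= vc_par[1]:
                vcmd = vc_par[3]
            else:
                vcmd = vc_par[2] + (vc_par[3] - vc_par[2]) * (
                    (tnext - vc_par[0]) / (vc_par[1] - vc_par[0]))
            for j in range(nclamp):
                c = clamp_comp[j]
                a0[j] = a[c]
                r0[j] = rhs[c]
                a[c] += BIG
                rhs[c] += BIG * vcmd

        # --- Hines solve (destroys a, rhs) ---
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = off[i] / a[i]
            a[p] -= f * off[i]
            rhs[p] -= f * rhs[i]
        vnew[0] = rhs[0] / a[0]
        for i in range(1, n):
            vnew[i] = (rhs[i] - off[i] * vnew[parent[i]]) / a[i]

        if not np.isfinite(vnew[0]) or abs(vnew[0]) > 500.0:
            return -(s + 1)

        # --- clamp current: residual of the unconstrained equations ---
        if nclamp > 0:
            for j in range(nclamp):
                csum[j] = 0.0
            for i in range(1, n):
                j = clamp_childrow[i]
                if j >= 0:
                    csum[j] += off[i] * vnew[i]
            iclamp = 0.0
            for j in range(nclamp):
                c = clamp_comp[j]
                res = a0[j] * vnew[c] - r0[j] + csum[j]
                if parent[c] >= 0:
                    res += off[c] * vnew[parent[c]]
                iclamp += res

        # --- sodium: channel influx + axial diffusion ---
        tot_influx = 0.0
        for i in range(n):
            if gna[i] > 0.0:
                ina = gna[i] * (0.5 * (v[i] + vnew[i]) - ena[i])  # nA, + = outward
                nai[i] += -ina * _NA_CONV / vol[i] * dt
                tot_influx += -ina * dt
        acc[0] += tot_influx
        for i in range(n):
            dam[i] = 0.0
        for i in range(1, n):
            if acoef[i] > 0.0:
                p = parent[i]
                flux = d_na * acoef[i] * (nai[p] - nai[i]) * dt
                dam[i] += flux
                dam[p] -= flux
        for i in range(n):
            nai[i] += dam[i] / vol[i]
            if nai[i] <= 0.0:
                return -(s + 1)

        for i in range(n):
            v[i] = vnew[i]

        # --- recording ---
        if (s + 1) % rec_every == 0:
            for j in range(rec_idx.shape[0]):
                vout[row, j] = v[rec_idx[j]]
            for g in range(gvol.shape[0]):
                naout[row, g] = 0.0
            for i in range(n):
                if group_id[i] >= 0:
                    naout[row, group_id[i]] += nai[i] * vol[i]
            for g in range(gvol.shape[0]):
                naout[row, g] /= gvol[g]
            iclamp_out[row] = iclamp
            row += 1
    return nsteps


# ---------------------------------------------------------------------------
# python-side model assembly
# ---------------------------------------------------------------------------


def _pack_na(model: GatingModel) -> np.ndarray:
    act, inact = model.activation, model.inactivation
    return np.array(
        [
            act.vhalf, act.k,
            act.tau.base, act.tau.amp, act.tau.vmid, act.tau.width,
            inact.vhalf, inact.k,
            inact.tau.base, inact.tau.amp, inact.tau.vmid, inact.tau.width,
            model.p_persist, float(model.act_exponent),
        ]
    )


def _pack_k(model: GatingModel) -> np.ndarray:
    act = model.activation
    return np.array(
        [
            act.vhalf, act.k,
            act.tau.base, act.tau.amp, act.tau.vmid, act.tau.width,
            float(model.act_exponent),
        ]
    )


_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=np.float64)


class CableSim:
    """A compiled model: geometry + channel layout ready for integration.

    Parameters
    ----------
    graph, layout
        Discretized morphology and channel densities/gating.
    v_rest
        Somatic resting potential; leak reversals are solved per compartment
        so that rest is an exact equilibrium.
    ena_mode
        'fixed' (Nernst at resting concentrations) or 'dynamic'.
    d_na
        Na+ diffusion coefficient, um^2/ms.
    tau_scale
        Multiplicative scale on all gating time constants (Q10-style
        exploration knob; default 1 = kinetics as parameterized at 18 degC).
    """

    def __init__(
        self,
        graph: CompartmentGraph,
        layout: ChannelLayout,
        *,
        v_rest: float = V_REST_DEFAULT,
        ena_mode: str = "fixed",
        d_na: float = D_NA_DEFAULT,
        na_i: float = NA_I_REST,
        na_o: float = NA_O_REST,
        ek: float = E_K,
        temperature_c: float = TEMPERATURE_C,
        tau_scale: float = 1.0,
    ):
        if ena_mode not in ("fixed", "dynamic"):
            raise ValueError("ena_mode must be 'fixed' or 'dynamic'")
        self.graph = graph
        self.layout = layout
        self.v_rest = float(v_rest)
        self.ena_mode = ena_mode
        self.d_na = float(d_na)
        self.na_i = float(na_i)
        self.na_o = float(na_o)
        self.ek = float(ek)
        self.temperature_c = float(temperature_c)
        self.tau_scale = float(tau_scale)
        self.rtf = 1e3 * 8.314462618 * (temperature_c + 273.15) / FARADAY
        self.ena = nernst(na_o, na_i, temperature_c=temperature_c)

        g = graph
        self.g12 = layout.conductance("nav12", g.area)
        self.g16 = layout.conductance("nav16", g.area)
        self.gkv = layout.conductance("kv", g.area)
        self.gkv1 = layout.conductance("kv1", g.area)
        self.gleak = layout.conductance("leak", g.area)
        if np.any(self.gleak <= 0):
            raise SimulationError(
                "zero leak conductance: leak reversal balance is unsolvable"
            )
        self.pna12 = _pack_na(layout.gating["nav12"])
        self.pna16 = _pack_na(layout.gating["nav16"])
        self.pkv = _pack_k(layout.gating["kv"])
        self.pkv1 = _pack_k(layout.gating["kv1"])

        # static axial structure
        self.gax_sum = g.g_axial.copy()
        np.add.at(self.gax_sum, g.parent[1:], g.g_axial[1:])

        # Na diffusion coupling (cross-section area / center distance, um)
        xsec = math.pi * g.diameter**2 / 4.0
        acoef = np.zeros(g.n)
        for i in range(1, g.n):
            p = g.parent[i]
            acoef[i] = 1.0 / (
                (g.length[i] / 2.0) / xsec[i] + (g.length[p] / 2.0) / xsec[p]
            )
        self.acoef = acoef

        # leak reversal balancing the resting currents exactly
        rest = self._gates_at(self.v_rest)
        gna_rest = self.g12 * rest["m12"] ** int(self.pna12[13]) * (
            self.pna12[12] + (1 - self.pna12[12]) * rest["h12"]
        ) + self.g16 * rest["m16"] ** int(self.pna16[13]) * (
            self.pna16[12] + (1 - self.pna16[12]) * rest["h16"]
        )
        gk_rest = self.gkv * rest["nk"] ** int(self.pkv[6]) + \
            self.gkv1 * rest["nk1"] ** int(self.pkv1[6])
        i_other = gna_rest * (self.v_rest - self.ena) + gk_rest * (self.v_rest - self.ek)
        self.eleak = self.v_rest + i_other / self.gleak

        self._group_id = np.array(
            [_GROUP_OF_REGION[REGIONS[c]] for c in g.region], dtype=np.int64
        )
        self._gvol = np.array(
            [g.volume[self._group_id == k].sum() for k in range(len(NA_GROUPS))]
        )
        self._gvol[self._gvol == 0] = 1.0

    # -- state ------------------------------------------------------------

    def _gates_at(self, v: float) -> dict[str, np.ndarray]:
        gat = self.layout.gating
        n = self.graph.n
        full = np.full
        return {
            "m12": full(n, float(steady_state_gate(gat["nav12"], "activation", v))),
            "h12": full(n, float(steady_state_gate(gat["nav12"], "inactivation", v))),
            "m16": full(n, float(steady_state_gate(gat["nav16"], "activation", v))),
            "h16": full(n, float(steady_state_gate(gat["nav16"], "inactivation", v))),
            "nk": full(n, float(steady_state_gate(gat["kv"], "activation", v))),
            "nk1": full(n, float(steady_state_gate(gat["kv1"], "activation", v))),
        }

    def initial_state(self) -> SimulationState:
        gates = self._gates_at(self.v_rest)
        return SimulationState(
            v=np.full(self.graph.n, self.v_rest),
            nai=np.full(self.graph.n, self.na_i),
            t=0.0,
            **gates,
        )

    # -- low-level advance -------------------------------------------------

    def advance(
        self,
        state: SimulationState,
        dt: float,
        nsteps: int,
        *,
        stims: Sequence[tuple[int, float, float, float]] = (),
        syns: Sequence[tuple[int, float, float, float, float, float]] = (),
        clamp_comp: np.ndarray | None = None,
        vc_par: np.ndarray | None = None,
        rec_idx: np.ndarray | None = None,
        rec_every: int = 1,
    ):
        """Advance `state` in place by nsteps of size dt; return recordings.

        Returns (times, vout, naout, iclamp_out, na_influx_total).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        g = self.graph
        if rec_idx is None:
            rec_idx = np.arange(0, dtype=np.int64)
        rec_idx = np.asarray(rec_idx, dtype=np.int64)
        nrec = nsteps // rec_every + 1
        vout = np.empty((nrec, len(rec_idx)))
        naout = np.empty((nrec, len(NA_GROUPS)))
        iclamp_out = np.zeros(nrec)
        acc = np.zeros(1)

        if stims:
            stim_comp = np.array([s[0] for s in stims], dtype=np.int64)
            stim_amp = np.array([s[1] for s in stims])
            stim_t0 = np.array([s[2] for s in stims])
            stim_t1 = np.array([s[3] for s in stims])
        else:
            stim_comp, stim_amp, stim_t0, stim_t1 = _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F
        if syns:
            syn_comp = np.array([s[0] for s in syns], dtype=np.int64)
            syn_gmax = np.array([s[1] for s in syns])
            syn_t0 = np.array([s[2] for s in syns])
            syn_taur = np.array([s[3] for s in syns])
            syn_taud = np.array([s[4] for s in syns])
            syn_e = np.array([s[5] for s in syns])
            tp = (syn_taur * syn_taud / (syn_taud - syn_taur)) * np.log(
                syn_taud / syn_taur)
            syn_norm = 1.0 / (np.exp(-tp / syn_taud) - np.exp(-tp / syn_taur))
        else:
            syn_comp = _EMPTY_I
            syn_gmax = syn_t0 = syn_taur = syn_taud = syn_norm = syn_e = _EMPTY_F

        if clamp_comp is None:
            clamp_comp = _EMPTY_I
            vc_par = np.zeros(4)
        clamp_comp = np.asarray(clamp_comp, dtype=np.int64)
        clamp_childrow = np.full(g.n, -1, dtype=np.int64)
        for j, c in enumerate(clamp_comp):
            clamp_childrow[g.parent == c] = j

        code = _integrate(
            state.v, state.m12, state.h12, state.m16, state.h16,
            state.nk, state.nk1, state.nai,
            g.parent, g.g_axial, self.gax_sum, g.capacitance, g.volume, self.acoef,
            self.g12, self.g16, self.gkv, self.gkv1, self.gleak, self.eleak,
            self.pna12, self.pna16, self.pkv, self.pkv1, self.tau_scale,
            self.ena, self.ek, self.ena_mode == "dynamic", self.na_o, self.rtf,
            self.d_na,
            stim_comp, stim_amp, stim_t0, stim_t1,
            syn_comp, syn_gmax, syn_t0, syn_taur, syn_taud, syn_norm, syn_e,
            clamp_comp, clamp_childrow, np.asarray(vc_par, dtype=float),
            state.t, dt, nsteps, rec_every,
            rec_idx, vout, self._group_id, self._gvol, naout, iclamp_out, acc,
        )
        if code < 0:
            t_fail = state.t + (-code) * dt
            worst = int(np.nanargmax(np.abs(state.v)))
            raise SimulationError(
                f"integration diverged at t = {t_fail:.6g} ms "
                f"(compartment {worst}, {g.section[worst]})"
            )
        times = state.t + np.arange(nrec) * (rec_every * dt)
        state.t += nsteps * dt
        return times, vout, naout, iclamp_out, float(acc[0])

    # -- site helpers ------------------------------------------------------

    def resolve_site(self, site) -> int:
        if isinstance(site, (int, np.integer)):
            if not (0 <= site < self.graph.n):
                raise KeyError(f"compartment {site} is off the tree")
            return int(site)
        region, offset = site
        return self.graph.locate(region, offset)

    def _axonal_record_sites(self, spacing: float = 2.0) -> np.ndarray:
        """Axonal compartments subsampled to ~`spacing` um, plus the soma center."""
        g = self.graph
        idx = np.where(g.axonal_mask())[0]
        order = np.argsort(g.distance[idx])
        idx = idx[order]
        picked = [self.resolve_site(("soma", 0.0))]
        next_d = 0.0
        for i in idx:
            if g.distance[i] >= next_d - 1e-9:
                picked.append(int(i))
                next_d = g.distance[i] + spacing
        return np.array(picked, dtype=np.int64)


# ---------------------------------------------------------------------------
# protocol-level operations
# ---------------------------------------------------------------------------


def initialize_state(
    graph: CompartmentGraph,
    layout: ChannelLayout,
    v_rest: float = V_REST_DEFAULT,
    **kw,
) -> tuple[CableSim, SimulationState]:
    """Build the compiled model and its equilibrium initial state."""
    sim = CableSim(graph, layout, v_rest=v_rest, **kw)
    return sim, sim.initial_state()


def step(sim: CableSim, state: SimulationState, dt: float = DT_DEFAULT,
         stimuli: Sequence = ()) -> SimulationState:
    """Advance the state by a single time step (in place; also returned)."""
    sim.advance(state, dt, 1, stims=stimuli)
    return state


def update_sodium(
    graph: CompartmentGraph,
    nai: np.ndarray,
    ina: np.ndarray,
    dt: float,
    d_na: float = D_NA_DEFAULT,
) -> np.ndarray:
    """One explicit step of the [Na+]_i update (reference implementation).

    d[Na]_i = -I_Na/(F * vol) + D * discrete Laplacian, sealed ends.  `ina`
    is the Na current per compartment in nA (positive outward).  Returns the
    new concentration array; raises if any concentration would go negative.
    """
    xsec = math.pi * graph.diameter**2 / 4.0
    new = nai + (-ina) * _NA_CONV / graph.volume * dt
    dam = np.zeros(graph.n)
    for i in range(1, graph.n):
        p = graph.parent[i]
        acoef = 1.0 / ((graph.length[i] / 2) / xsec[i] + (graph.length[p] / 2) / xsec[p])
        flux = d_na * acoef * (new[p] - new[i]) * dt
        dam[i] += flux
        dam[p] -= flux
    new = new + dam / graph.volume
    if np.any(new <= 0):
        raise SimulationError("negative [Na]_i: time step too large")
    return new


def _traceset_from_v(sim, times, vout, rec_idx, extra_channels=(), meta=None):
    g = sim.graph
    channels = list(extra_channels)
    for j, i in enumerate(rec_idx):
        region = REGIONS[g.region[i]]
        dist = g.distance[i]
        channels.append(
            Channel(
                name=f"V_{g.section[i]}_{dist:.1f}um" if region != "soma" else "V_soma",
                samples=vout[:, j],
                quantity="V",
                distance=float(dist),
                region=region,
            )
        )
    return TraceSet(time=times, channels=channels, meta=meta or {})


def run_current_clamp(
    sim: CableSim,
    protocols: Protocol | Sequence[Protocol],
    record_sites: Sequence = (("soma", 0.0),),
    *,
    dt: float = DT_DEFAULT,
    t_total: float | None = None,
    rec_interval: float = 0.025,
    record_na: bool = False,
) -> TraceSet:
    """Somatic current injection; step families map to one V channel per sweep.

    For a family (several protocols), each protocol is run from the same
    resting initial condition and the channels carry the sweep index and the
    step amplitude in the trace-set metadata.
    """
    if isinstance(protocols, Protocol):
        protocols = [protocols]
    rec_idx = np.array([sim.resolve_site(s) for s in record_sites], dtype=np.int64)
    rec_every = max(1, round(rec_interval / dt))
    channels = []
    amps = []
    times = None
    na_channels = []
    for sweep, proto in enumerate(protocols):
        if proto.kind not in ("current_step", "brief_pulse_train"):
            raise ValueError("run_current_clamp takes current protocols")
        site = sim.resolve_site(proto.site)
        stims = []
        for k in range(proto.n_pulses):
            t0 = proto.t_start + k * proto.interval
            stims.append((site, proto.amplitude, t0, t0 + proto.duration))
        total = t_total or (proto.t_start + proto.duration + 100.0)
        nsteps = round(total / dt)
        state = sim.initial_state()
        t_arr, vout, naout, _, _ = sim.advance(
            state, dt, nsteps, stims=stims, rec_idx=rec_idx, rec_every=rec_every
        )
        times = t_arr
        amps.append(proto.amplitude)
        for j, i in enumerate(rec_idx):
            g = sim.graph
            name = f"V_sweep{sweep}_{g.section[i]}"
            channels.append(
                Channel(
                    name=name,
                    samples=vout[:, j],
                    quantity="V",
                    distance=float(g.distance[i]),
                    region=REGIONS[g.region[i]],
                    sweep=sweep,
                )
            )
        if record_na:
            for gi, gname in enumerate(NA_GROUPS):
                na_channels.append(
                    Channel(
                        name=f"Nai_sweep{sweep}_{gname}",
                        samples=naout[:, gi],
                        quantity="Na_i",
                        region=gname,
                        sweep=sweep,
                    )
                )
    return TraceSet(
        time=times,
        channels=channels + na_channels,
        meta={"protocol": "current_clamp", "amplitudes_nA": amps,
              "pulse_ms": [protocols[0].t_start, protocols[0].t_start + protocols[0].duration]},
    )


def run_voltage_ramp(
    sim: CableSim,
    ramp: Protocol | None = None,
    *,
    dt: float = 0.02,
    rec_interval: float = 0.1,
) -> TraceSet:
    """Ideal somatic voltage-clamp ramp; returns clamp current and regional
    [Na+]_i aggregates (fluorescence proxies).

    The command is imposed on every soma compartment.  The default ramp is
    the 2 s, -70 -> 0 mV protocol.  A coarser time step than the AP default
    is adequate because the dynamics tracked under subthreshold clamp are
    slow; the step is configurable.
    """
    ramp = ramp or Protocol.voltage_ramp()
    if ramp.kind != "voltage_ramp":
        raise ValueError("run_voltage_ramp takes a voltage_ramp protocol")
    g = sim.graph
    clamp_comp = np.where(g.region_mask("soma"))[0].astype(np.int64)
    t_total = ramp.t_start + ramp.duration + 10.0
    nsteps = round(t_total / dt)
    rec_every = max(1, round(rec_interval / dt))
    vc_par = np.array([ramp.t_start, ramp.t_start + ramp.duration,
                       ramp.v_start, ramp.v_end])
    state = sim.initial_state()
    state.v[clamp_comp] = ramp.v_start
    times, vout, naout, iclamp, _ = sim.advance(
        state, dt, nsteps,
        clamp_comp=clamp_comp, vc_par=vc_par,
        rec_idx=clamp_comp[:1], rec_every=rec_every,
    )
    vcmd = np.interp(
        times, [ramp.t_start, ramp.t_start + ramp.duration],
        [ramp.v_start, ramp.v_end],
    )
    channels = [
        Channel(name="Vcmd", samples=vcmd, quantity="Vcmd", region="soma", distance=0.0),
        Channel(name="I_clamp", samples=iclamp, quantity="I_clamp", region="soma",
                distance=0.0),
    ]
    for gi, gname in enumerate(NA_GROUPS):
        channels.append(
            Channel(name=f"Nai_{gname}", samples=naout[:, gi], quantity="Na_i",
                    region=gname)
        )
    return TraceSet(
        time=times,
        channels=channels,
        meta={
            "protocol": "voltage_ramp",
            "ramp": {"t0": ramp.t_start, "t1": ramp.t_start + ramp.duration,
                     "v_start": ramp.v_start, "v_end": ramp.v_end},
            "ena_mV": sim.ena,
        },
    )


def run_propagation_protocol(
    sim: CableSim,
    pulse: Protocol | None = None,
    *,
    dt: float = DT_DEFAULT,
    t_total: float = 15.0,
    spacing: float = 2.0,
    rec_interval: float = 0.005,
    dendrite_sites: Sequence = (("apical", 50.0), ("apical", 150.0)),
) -> TraceSet:
    """Single-AP simulation recording V along the whole axon at <= `spacing`
    um intervals and <= 5 us sampling, for delay-distance analysis.

    A subthreshold pulse yields a trace set flagged ``meta['ap'] = False``
    rather than an exception.
    """
    pulse = pulse or Protocol.brief_pulse(amplitude=2.0)
    soma_idx = sim.resolve_site(("soma", 0.0))
    site = sim.resolve_site(pulse.site)
    rec_idx = sim._axonal_record_sites(spacing)
    dend = [sim.resolve_site(s) for s in dendrite_sites]
    rec_idx = np.concatenate([rec_idx, np.array(dend, dtype=np.int64)])
    rec_every = max(1, round(rec_interval / dt))
    nsteps = round(t_total / dt)
    state = sim.initial_state()
    times, vout, _, _, _ = sim.advance(
        state, dt, nsteps,
        stims=[(site, pulse.amplitude, pulse.t_start, pulse.t_start + pulse.duration)],
        rec_idx=rec_idx, rec_every=rec_every,
    )
    soma_col = int(np.where(rec_idx == soma_idx)[0][0])
    has_ap = bool(vout[:, soma_col].max() > 0.0)
    ts = _traceset_from_v(
        sim, times, vout, rec_idx,
        meta={"protocol": "propagation", "ap": has_ap,
              "pulse": {"amplitude_nA": pulse.amplitude, "t_start": pulse.t_start,
                        "duration_ms": pulse.duration}},
    )
    return ts
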