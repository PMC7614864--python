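"""Protocol-driven integration of the cable + gating + calcium system.

The voltage system advances by an implicit (backward-Euler) step solved
directly on the Hines-ordered compartment tree, gates by exponential Euler
and calcium by an operator-split sub-step, all at a fixed step size
(default 25 µs). Stimuli are current injections at named sites (step
pulses, pulse trains, chirp, arbitrary waveforms) or presynaptic event
trains delivered to placed synapses; recordings are uniformly sampled
:class:`Trace` objects tagged by site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ca3deg import _core
from ca3deg.calcium import CalciumConfig, init_calcium, shell_geometry
from ca3deg.channels import default_kinetics, assign_conductances, gate_inf, gate_tau

__all__ = [
    "SolverConfig",
    "Protocol",
    "StepStim",
    "TrainStim",
    "WaveStim",
    "Trace",
    "CellState",
    "SimulationDiverged",
    "make_chirp",
    "compile_cell",
    "stabilize",
    "run",
]

CHANNEL_ORDER = (
    "NaF", "KDR", "KA_prox", "KA_dist", "KM",
    "CaL", "CaN", "CaT", "SK", "BK", "HCN",
)


class SimulationDiverged(RuntimeError):
    def __init__(self, t_ms: float):
        super().__init__(f"simulation diverged at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


@dataclass
class SolverConfig:
    """Integration settings. ``dt_us`` must be <= 25 µs."""

    dt_us: float = 25.0
    v_init: float = -65.0  # mV
    e_leak: float = -61.0  # mV
    record_stride: int = 1
    kinetics: dict | None = None
    ca_config: CalciumConfig | None = None

    def __post_init__(self):
        if self.dt_us > 25.0 + 1e-9:
            raise ValueError("dt must be <= 25 us")


@dataclass
class StepStim:
    """Constant current step at a site. Amplitude in nA, times in ms."""

    site: object  # 'soma' | ('apical', path_um) | compartment index
    amp_nA: float
    onset_ms: float
    dur_ms: float


@dataclass
class TrainStim:
    """Train of identical rectangular pulses (CSB-style)."""

    site: object
    amp_nA: float
    n_pulses: int
    width_ms: float
    gap_ms: float
    onset_ms: float = 0.0


@dataclass
class WaveStim:
    """Arbitrary waveform (nA) sampled at the solver step, from ``onset_ms``."""

    site: object
    wave_nA: np.ndarray
    onset_ms: float = 0.0


@dataclass
class Protocol:
    """Settle period plus stimulus events and recording sites.

    ``record_sites`` are voltage sites ('soma', ('apical', µm) or indices);
    ``record_ca_sites`` record outer-shell calcium. ``syn_event_times_ms``
    (relative to the end of settling) drive any placed synapses
    synchronously. The settle period (default 5 s) precedes all stimuli and
    is included in the recordings (t = 0 at the start of settling).
    """

    settle_s: float = 5.0
    stimuli: list = field(default_factory=list)
    record_sites: tuple = ("soma",)
    record_ca_sites: tuple = ()
    syn_event_times_ms: np.ndarray | None = None
    post_ms: float = 0.0  # extra quiet time after the last stimulus


@dataclass
class Trace:
    """Uniformly sampled recording: values, dt/t0 in seconds, site, unit."""

    samples: np.ndarray
    dt: float
    t0: float
    site: str
    unit: str

    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.samples))


@dataclass
class CellState:
    v: np.ndarray
    gates: np.ndarray
    ca: np.ndarray
    buf: np.ndarray
    bound: np.ndarray
    syn: np.ndarray

    def copy(self) -> "CellState":
        return CellState(*(a.copy() for a in
                           (self.v, self.gates, self.ca, self.buf, self.bound,
                            self.syn)))


def make_chirp(amplitude_pp: float = 100.0, f0: float = 0.0, f1: float = 15.0,
               duration: float = 15.0, dt: float = 25e-6) -> np.ndarray:
    """Constant-amplitude chirp current, returned in pA.

    Sinusoid whose instantaneous frequency rises linearly from ``f0`` to
    ``f1`` Hz over ``duration`` seconds; ``amplitude_pp`` is peak-to-peak
    in pA. ``dt`` in seconds. Raises if the sampling gives fewer than 20
    samples per cycle at ``f1``.
    """
    if not f1 > f0 >= 0:
        raise ValueError("need f1 > f0 >= 0")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt * f1 * 20.0 > 1.0:
        raise ValueError("dt too coarse: fewer than 20 samples per cycle at f1")
    t = np.arange(int(round(duration / dt))) * dt
    phase = 2.0 * math.pi * (f0 * t + (f1 - f0) * t * t / (2.0 * duration))
    return (amplitude_pp / 2.0) * np.sin(phase)


def chirp_instantaneous_frequency(t: float, f0: float = 0.0, f1: float = 15.0,
                                  duration: float = 15.0) -> float:
    """Analytic phase-derivative frequency of the chirp at time ``t`` (s)."""
    return f0 + (f1 - f0) * min(t, duration) / duration


class CompiledCell:
    """Flat-array form of (morphology, parameters, kinetics) for the kernel."""

    def __init__(self, model, params, config: SolverConfig):
        self.model = model
        self.params = params
        self.config = config
        kin = config.kinetics if config.kinetics is not None else default_kinetics()
        self.kinetics = kin
        cac = config.ca_config
        if cac is None:
            cac = CalciumConfig(totbuf=params.totbuf, totpp=params.totpp)
        else:
            cac = replace(cac, totbuf=params.totbuf, totpp=params.totpp)
        self.ca_config = cac
        self.dt_ms = config.dt_us * 1e-3

        n = model.n_comp
        dens = assign_conductances(model, params, kin)
        # axial conductances scale with the model's axial resistivity
        self.g_ax = model.g_axial_uS * (model.r_a / params.r_a)
        self.c_nF = model.c_m * model.area_cm2 * 1e3
        self.area6 = model.area_cm2 * 1e6
        self.g_leak_uS = self.area6 / (params.r_m * 1e3)  # 1/(kOhm cm2) -> S/cm2

        laws, erevs, gbar = [], [], []
        gate_rows = []
        for ci, name in enumerate(CHANNEL_ORDER):
            spec = kin[name]
            laws.append(0 if spec.law == "ohmic" else 1)
            erevs.append(spec.e_rev if spec.e_rev is not None else 0.0)
            gbar.append(dens[name])
            for g in spec.gates:
                gate_rows.append((ci, g))
        self.chan_law = np.array(laws, dtype=np.int64)
        self.chan_erev = np.array(erevs, dtype=float)
        self.gbar = np.array(gbar, dtype=float)

        ngate = len(gate_rows)
        NV = _core.NV
        vg = _core.vgrid()
        self.gate_chan = np.empty(ngate, dtype=np.int64)
        self.gate_power = np.empty(ngate, dtype=np.int64)
        self.gate_kind = np.empty(ngate, dtype=np.int64)
        self.inf_tab = np.zeros((ngate, NV))
        self.etau_tab = np.ones((ngate, NV))
        self.gate_p1 = np.zeros(ngate)
        self.gate_p2 = np.zeros(ngate)
        self.gate_p3 = np.zeros(ngate)
        self.gate_p4 = np.zeros(ngate)
        self.gate_etau_c = np.ones(ngate)
        self._gate_specs = [g for _, g in gate_rows]
        for gi, (ci, g) in enumerate(gate_rows):
            self.gate_chan[gi] = ci
            self.gate_power[gi] = g.power
            if g.depends == "v":
                self.gate_kind[gi] = 0
                self.inf_tab[gi] = gate_inf(g, vg)
                self.etau_tab[gi] = np.exp(-self.dt_ms / gate_tau(g, vg))
            elif g.depends == "ca":
                self.gate_kind[gi] = 1
                self.gate_p1[gi] = g.inf["kd"]
                self.gate_p2[gi] = g.inf["n"]
                self.gate_etau_c[gi] = math.exp(
                    -self.dt_ms / float(g.tau["value"])
                )
            else:  # v_ca_shift
                self.gate_kind[gi] = 2
                self.gate_p1[gi] = g.inf["vhalf"]
                self.gate_p2[gi] = g.inf["k"]
                self.gate_p3[gi] = g.inf["shift_per_decade"]
                self.gate_p4[gi] = g.inf["ca_ref"]
                self.gate_etau_c[gi] = math.exp(
                    -self.dt_ms / float(g.tau["value"])
                )

        self.tabA2, self.tabB2 = _core.ghk_tables(2)
        self.tabA1, self.tabB1 = _core.ghk_tables(1)

        geom = shell_geometry(model)
        self.shell_vol = geom["shell_vol"]
        th = geom["thickness"]
        self.rad_geo = geom["iface_area"] / (0.5 * (th[:, 1:] + th[:, :3]))
        self.th0 = th[:, 0]
        lon = np.zeros((n, 4))
        if n > 1:
            par = model.parent[1:]
            dx = 0.5 * (model.length[1:] + model.length[par])
            lon[1:] = np.minimum(
                geom["cross_area"][1:], geom["cross_area"][par]
            ) / dx[:, None]
        self.lon_geo = lon
        self.pump_a = np.full(
            n, cac.totpp * cac.pump_vmax_unit
        ) / self.th0
        # calcium operator substep: bounded by the explicit radial
        # diffusion stability limit of the thinnest shell
        d_max = max(cac.d_ca, cac.d_buf)
        limit_ms = float(np.min(th)) ** 2 / (2.0 * d_max) * 0.5
        self.ca_every = int(max(1, min(4, limit_ms / self.dt_ms)))

        # synapse aggregation (set via attach_synapses)
        self.syn_pA = np.zeros(n)
        self.syn_pN = np.zeros(n)
        self.tau_rA, self.tau_dA = 2.0, 10.0
        self.tau_rN, self.tau_dN = 5.0, 50.0

    def attach_synapses(self, synapses) -> None:
        """Aggregate per-compartment AMPA/NMDA permeabilities (cm³/s)."""
        self.syn_pA[:] = 0.0
        self.syn_pN[:] = 0.0
        for s in synapses:
            self.syn_pA[s.comp] += s.p_ampa
            self.syn_pN[s.comp] += s.p_nmda
        if synapses:
            s0 = synapses[0]
            self.tau_rA, self.tau_dA = s0.tau_r_ampa, s0.tau_d_ampa
            self.tau_rN, self.tau_dN = s0.tau_r_nmda, s0.tau_d_nmda

    def init_state(self) -> CellState:
        n = self.model.n_comp
        v = np.full(n, self.config.v_init)
        cast = init_calcium(self.model, self.ca_config)
        gates = np.empty((len(self._gate_specs), n))
        for gi, g in enumerate(self._gate_specs):
            if g.depends == "v":
                gates[gi] = gate_inf(g, v)
            elif g.depends == "ca":
                gates[gi] = gate_inf(g, None, ca=cast.ca[:, 0])
            else:
                gates[gi] = gate_inf(g, v, ca=cast.ca[:, 0])
        return CellState(
            v=v, gates=gates, ca=cast.ca, buf=cast.buf, bound=cast.bound,
            syn=np.zeros(4),
        )

    def resolve_site(self, site) -> int:
        if isinstance(site, (int, np.integer)):
            if not 0 <= site < self.model.n_comp:
                raise KeyError(f"no compartment {site}")
            return int(site)
        if site == "soma":
            return 0
        region, dist = site
        return self.model.nearest_compartment(float(dist), region=region)

    @staticmethod
    def site_tag(site) -> str:
        if isinstance(site, (int, np.integer)):
            return f"comp_{int(site)}"
        if site == "soma":
            return "soma"
        region, dist = site
        return f"{region}_{int(round(dist))}"

    def integrate(self, state: CellState, n_steps: int, inj_comp, inj_wave,
                  ev_steps, rec_v_comp, rec_ca_comp, rec_stride: int):
        norm_A = dblexp_norm_factor(self.tau_rA, self.tau_dA)
        norm_N = dblexp_norm_factor(self.tau_rN, self.tau_dN)
        cac = self.ca_config
        return _core.integrate(
            self.model.parent, self.g_ax, self.c_nF, self.area6,
            self.g_leak_uS, self.config.e_leak,
            self.chan_law, self.chan_erev, self.gbar,
            self.gate_chan, self.gate_power, self.gate_kind,
            self.inf_tab, self.etau_tab,
            self.gate_p1, self.gate_p2, self.gate_p3, self.gate_p4,
            self.gate_etau_c,
            self.tabA2, self.tabB2, self.tabA1, self.tabB1,
            self.shell_vol, self.rad_geo, self.lon_geo, self.th0,
            cac.d_ca, cac.d_buf, cac.k_on, cac.k_off,
            self.pump_a, cac.pump_km, cac.ca_rest,
            self.syn_pA, self.syn_pN,
            ev_steps, self.tau_rA, self.tau_dA, self.tau_rN, self.tau_dN,
            norm_A, norm_N,
            inj_comp, inj_wave,
            self.dt_ms, n_steps, rec_stride, self.ca_every,
            rec_v_comp, rec_ca_comp,
            state.v, state.gates, state.ca, state.buf, state.bound, state.syn,
        )


def dblexp_norm_factor(tau_r: float, tau_d: float) -> float:
    """Normalization making the double-exponential kernel peak exactly 1."""
    if not tau_d > tau_r > 0:
        raise ValueError("need tau_d > tau_r > 0")
    tpk = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    return 1.0 / (math.exp(-tpk / tau_d) - math.exp(-tpk / tau_r))


def compile_cell(model, params, config: SolverConfig | None = None,
                 synapses=None) -> CompiledCell:
    cell = CompiledCell(model, params, config or SolverConfig())
    if synapses:
        cell.attach_synapses(synapses)
    return cell


def _build_injection(cell: CompiledCell, protocol: Protocol, n_steps: int,
                     settle_steps: int):
    dt_ms = cell.dt_ms
    rows: dict[int, np.ndarray] = {}

    def row(comp):
        if comp not in rows:
            rows[comp] = np.zeros(n_steps)
        return rows[comp]

    for stim in protocol.stimuli:
        comp = cell.resolve_site(stim.site)
        r = row(comp)
        if isinstance(stim, StepStim):
            i0 = settle_steps + int(round(stim.onset_ms / dt_ms))
            i1 = i0 + int(round(stim.dur_ms / dt_ms))
            r[i0:min(i1, n_steps)] += stim.amp_nA
        elif isinstance(stim, TrainStim):
            period = stim.width_ms + stim.gap_ms
            for k in range(stim.n_pulses):
                on = stim.onset_ms + k * period
                i0 = settle_steps + int(round(on / dt_ms))
                i1 = i0 + int(round(stim.width_ms / dt_ms))
                r[i0:min(i1, n_steps)] += stim.amp_nA
        elif isinstance(stim, WaveStim):
            i0 = settle_steps + int(round(stim.onset_ms / dt_ms))
            w = np.asarray(stim.wave_nA, dtype=float)
            i1 = min(i0 + len(w), n_steps)
            r[i0:i1] += w[: i1 - i0]
        else:
            raise TypeError(f"unknown stimulus type {type(stim).__name__}")
    if not rows:
        return np.zeros(0, dtype=np.int64), np.zeros((0, n_steps))
    comps = np.array(sorted(rows), dtype=np.int64)
    wave = np.stack([rows[c] for c in comps])
    return comps, wave


def _protocol_duration_ms(protocol: Protocol) -> float:
    end = 0.0
    for stim in protocol.stimuli:
        if isinstance(stim, StepStim):
            end = max(end, stim.onset_ms + stim.dur_ms)
        elif isinstance(stim, TrainStim):
            end = max(end, stim.onset_ms + stim.n_pulses *
                      (stim.width_ms + stim.gap_ms))
        elif isinstance(stim, WaveStim):
            end = max(end, stim.onset_ms + len(stim.wave_nA) * 0.025)
    if protocol.syn_event_times_ms is not None and len(protocol.syn_event_times_ms):
        end = max(end, float(np.max(protocol.syn_event_times_ms)) + 400.0)
    return end + protocol.post_ms


def run(model, params, protocol: Protocol, config: SolverConfig | None = None,
        synapses=None, init_state: CellState | None = None,
        cell: CompiledCell | None = None) -> dict:
    """Integrate a protocol and return ``{site tag: Trace}``.

    The settle period runs first (from ``init_state`` if given, else from
    rest initialization); recordings span settle + stimulus. Raises
    :class:`SimulationDiverged` on non-finite state.
    """
    if cell is None:
        cell = compile_cell(model, params, config, synapses)
    elif synapses:
        cell.attach_synapses(synapses)
    dt_ms = cell.dt_ms
    settle_steps = int(round(protocol.settle_s * 1e3 / dt_ms))
    stim_ms = _protocol_duration_ms(protocol)
    n_steps = settle_steps + int(round(stim_ms / dt_ms))
    if n_steps == 0:
        raise ValueError("empty protocol")

    inj_comp, inj_wave = _build_injection(cell, protocol, n_steps, settle_steps)
    if protocol.syn_event_times_ms is not None:
        ev = settle_steps + np.round(
            np.asarray(protocol.syn_event_times_ms, dtype=float) / dt_ms
        ).astype(np.int64)
        ev_steps = np.sort(ev)
        if len(ev_steps) and not (cell.syn_pA.any() or cell.syn_pN.any()):
            raise ValueError("synaptic events scheduled but no synapses attached")
    else:
        ev_steps = np.zeros(0, dtype=np.int64)

    rec_v_comp = np.array(
        [cell.resolve_site(s) for s in protocol.record_sites], dtype=np.int64
    )
    rec_ca_comp = np.array(
        [cell.resolve_site(s) for s in protocol.record_ca_sites], dtype=np.int64
    )
    state = init_state.copy() if init_state is not None else cell.init_state()
    stride = cell.config.record_stride

    rec_v, rec_ca, status, fail_step = cell.integrate(
        state, n_steps, inj_comp, inj_wave, ev_steps,
        rec_v_comp, rec_ca_comp, stride,
    )
    if status != _core.STATUS_OK:
        raise SimulationDiverged(fail_step * dt_ms)

    dt_s = dt_ms * 1e-3 * stride
    out = {}
    for k, site in enumerate(protocol.record_sites):
        tag = cell.site_tag(site)
        out[tag] = Trace(rec_v[k], dt_s, 0.0, tag, "mV")
    for k, site in enumerate(protocol.record_ca_sites):
        tag = "ca_" + cell.site_tag(site)
        out[tag] = Trace(rec_ca[k], dt_s, 0.0, tag, "mM")
    out["_state"] = state
    return out


def stabilize(model, params, duration_s: float = 5.0,
              config: SolverConfig | None = None,
              cell: CompiledCell | None = None):
    """Stimulus-free integration from rest; returns (state, residual dV/dt).

    ``residual`` is the maximum somatic |dV/dt| (mV/ms) over the final 10 ms;
    a warning flag (residual > 1e-3 mV/ms) marks non-settling, e.g.
    spontaneously spiking, models. ``duration_s = 0`` returns the initial
    condition unchanged.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    if cell is None:
        cell = compile_cell(model, params, config)
    state = cell.init_state()
    if duration_s == 0:
        return state, 0.0, False
    proto = Protocol(settle_s=duration_s, stimuli=[], record_sites=("soma",))
    traces = run(model, params, proto, cell=cell, init_state=state)
    v = traces["soma"].samples
    tail = max(2, int(round(10e-3 / traces["soma"].dt)))
    dvdt = np.diff(v[-tail:]) / (traces["soma"].dt * 1e3)
    residual = float(np.max(np.abs(dvdt))) if len(dvdt) else 0.0
    return traces["_state"], residual, residual > 1e-3


def export_traces_h5(traces: dict, path) -> None:
    """Write a trace dict to an HDF5 file with dt/site/unit metadata."""
    import h5py

    with h5py.File(path, "w") as h5:
        for tag, tr in traces.items():
            if tag.startswith("_"):
                continue
            ds = h5.create_dataset(tag, data=np.asarray(tr.samples))
            ds.attrs["dt_s"] = tr.dt
            ds.attrs["t0_s"] = tr.t0
            ds.attrs["site"] = tr.site
            ds.attrs["unit"] = tr.unit


def export_traces_csv(traces: dict, path, stride: int = 1) -> None:
    """Write a trace dict to delimited text (time + one column per site)."""
    import pandas as pd

    cols = {}
    t = None
    for tag, tr in traces.items():
        if tag.startswith("_"):
            continue
        if t is None:
            t = tr.time()[::stride]
        cols[f"{tag} ({tr.unit})"] = np.asarray(tr.samples)[::stride]
    df = pd.DataFrame({"time_s": t, **cols})
    df.to_csv(path, index=False)
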