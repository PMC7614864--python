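"""Virtual knockout models (VKM): single-mechanism deletions and their impact.

A virtual knockout re-simulates a validated model with exactly one maximal
conductance (or the NMDAR permeability) set to zero, leaving every other
parameter, the synapse placement and the protocol untouched. NaF and KDR
are excluded so that every knockout model can still generate action
potentials. Effects are reported as percentage changes of the CSB
measurements (ΔV_AP, V_ramp, CSB rate) relative to the intact base model,
and — for the NMDAR knockout under synaptic stimulation — as paired
synapse-local calcium traces with and without NMDARs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ca3deg import simulator as sim
from ca3deg.csb import CSB_PROTOCOLS, CSBCriteria, run_csb_protocol, score_csb_traces

__all__ = [
    "KNOCKOUT_TARGETS",
    "KnockoutSpec",
    "make_knockout",
    "schedule_vkm",
    "percent_change",
    "calcium_comparison",
    "run_vkm",
]

#: channel knockouts allowed (NaF/KDR excluded to preserve AP generation)
KNOCKOUT_TARGETS = ("KA", "KM", "CaL", "CaN", "CaT", "SK", "BK", "HCN", "NMDAR")

_PARAM_OF_TARGET = {
    "KA": "g_ka", "KM": "g_km", "CaL": "g_cal", "CaN": "g_can",
    "CaT": "g_cat", "SK": "g_sk", "BK": "g_bk", "HCN": "g_h",
}


@dataclass(frozen=True)
class KnockoutSpec:
    target: str
    protocol: str  # a CSB protocol name

    def __post_init__(self):
        if self.target not in KNOCKOUT_TARGETS:
            raise ValueError(
                f"target {self.target!r} not in {KNOCKOUT_TARGETS} "
                "(NaF and KDR are excluded to allow AP generation)"
            )
        if self.protocol not in CSB_PROTOCOLS:
            raise ValueError(f"unknown CSB protocol {self.protocol!r}")


def make_knockout(params, synapses, target: str):
    """Zero exactly one mechanism; everything else is untouched.

    Returns ``(params_ko, synapses_ko)``. Channel targets zero the
    corresponding maximal conductance in the parameter vector; the NMDAR
    target zeroes every synapse's NMDA permeability while leaving AMPA
    intact. Raises on NaF/KDR.
    """
    if target in ("NaF", "KDR"):
        raise ValueError(f"{target} is excluded from knockout analyses")
    if target not in KNOCKOUT_TARGETS:
        raise ValueError(f"unknown knockout target {target!r}")
    if target == "NMDAR":
        if not synapses:
            raise ValueError("NMDAR knockout requires placed synapses")
        return params, [replace(s, p_nmda=0.0) for s in synapses]
    return replace(params, **{_PARAM_OF_TARGET[target]: 0.0}), synapses


def schedule_vkm(model_ids, targets) -> list:
    """Cartesian product of models and knockout targets (the VKM run list)."""
    model_ids = list(model_ids)
    targets = list(targets)
    if not model_ids or not targets:
        raise ValueError("need a non-empty population and target set")
    for t in targets:
        if t not in KNOCKOUT_TARGETS:
            raise ValueError(f"unknown knockout target {t!r}")
    return [(m, t) for m in model_ids for t in targets]


def percent_change(base: float, vkm: float) -> float:
    """100 * (knockout - base) / base; NaN (undefined) when base is 0."""
    if base == 0 or not np.isfinite(base):
        return np.nan
    return 100.0 * (vkm - base) / base


def run_vkm(model, params, targets, protocol: str,
            synapses=None, config: sim.SolverConfig | None = None,
            criteria: CSBCriteria | None = None,
            settle_s: float = 5.0) -> pd.DataFrame:
    """Knock out each target in turn and report CSB changes vs base.

    One row per target with the base and knockout ΔV_AP / V_ramp / CSB
    rate and their percentage changes. The base and every knockout share
    the same protocol, settle duration and synapse placement.
    """
    spec = CSB_PROTOCOLS[protocol]
    if spec.kind != "synaptic" and "NMDAR" in targets:
        raise ValueError("NMDAR knockout applies only to synaptic stimulation")

    def evaluate(pr, syns):
        cell = sim.compile_cell(model, pr, config, synapses=syns)
        state, _, _ = sim.stabilize(model, pr, settle_s, cell=cell)
        v_rmp = float(state.v[0])
        traces = run_csb_protocol(
            model, pr, spec, synapses=syns, init_state=state, cell=cell
        )
        return score_csb_traces(traces, spec, v_rmp, criteria, settle_s=0.0)

    base = evaluate(params, synapses)
    rows = []
    for target in targets:
        p_ko, s_ko = make_knockout(params, synapses, target)
        ko = evaluate(p_ko, s_ko)
        rows.append({
            "target": target,
            "protocol": protocol,
            "base_dv_ap": base.mean_dv_ap(),
            "base_v_ramp": base.mean_v_ramp(),
            "base_rate": base.rate,
            "ko_dv_ap": ko.mean_dv_ap(),
            "ko_v_ramp": ko.mean_v_ramp(),
            "ko_rate": ko.rate,
            "pct_dv_ap": percent_change(base.mean_dv_ap(), ko.mean_dv_ap()),
            "pct_v_ramp": percent_change(base.mean_v_ramp(), ko.mean_v_ramp()),
            "pct_rate": percent_change(base.rate, ko.rate),
        })
    return pd.DataFrame(rows)


def calcium_comparison(model, params, synapses,
                       config: sim.SolverConfig | None = None,
                       settle_s: float = 5.0):
    """Paired synapse-local calcium traces with and without NMDARs.

    Runs the synaptic CSB protocol twice — intact and with NMDAR
    permeability zeroed — on identical synapse placement, and returns
    ``(trace_with, trace_without)`` for the calcium pool of the
    highest-synapse-density compartment.
    """
    if not synapses:
        raise ValueError("calcium comparison requires placed synapses")
    spec = CSB_PROTOCOLS["synaptic5Hz"]

    def one(syns):
        cell = sim.compile_cell(model, params, config, synapses=syns)
        state, _, _ = sim.stabilize(model, params, settle_s, cell=cell)
        traces = run_csb_protocol(
            model, params, spec, synapses=syns, init_state=state, cell=cell
        )
        ca_keys = [k for k in traces if k.startswith("ca_")]
        return traces[ca_keys[0]]

    _, syn_ko = make_knockout(params, synapses, "NMDAR")
    return one(synapses), one(syn_ko)
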