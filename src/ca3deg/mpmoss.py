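"""Multi-parametric multi-objective stochastic search (MPMOSS).

Uniform random sampling of the 14-dimensional parameter space (two passive
constants, ten maximal channel conductances/permeability scales, two
calcium-handling densities), full measurement evaluation of every sampled
model, and rejection against the electrophysiological bounds: a model is
valid iff all 11 validation measurements fall inside their bounds
(inclusive).

Rows are independent tasks: each row's sub-seed derives from
(global seed, row index), so populations are reproducible and any stored
row can be re-simulated bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from ca3deg import simulator as sim
from ca3deg.measurements import (
    MeasurementBounds,
    MeasurementVector,
    VALIDATION_FIELDS,
    ap_measurements,
    bap_amplitudes,
    measure_rin,
    measure_rmp_sd,
    measure_sag,
    impedance_profile,
)

__all__ = [
    "ParameterVector",
    "TABLE1_BOUNDS",
    "sample_parameters",
    "validate",
    "measure_model",
    "run_search",
]


@dataclass
class ParameterVector:
    """The 14 search parameters, at their base values by default.

    Units: r_m kΩ·cm², r_a Ω·cm, channel maxima mS/cm² except g_h in
    µS/cm², totpp/totbuf calcium pump and buffer density scales (totbuf in
    mM).
    """

    r_m: float = 60.0
    r_a: float = 200.0
    g_na: float = 15.0
    g_kdr: float = 11.0
    g_h: float = 1.0
    g_ka: float = 0.1
    g_cal: float = 2.5
    g_cat: float = 0.25
    g_can: float = 2.5
    g_km: float = 0.01
    g_bk: float = 0.8
    g_sk: float = 0.5
    totpp: float = 0.2
    totbuf: float = 1.2

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


#: uniform sampling ranges of the stochastic search
TABLE1_BOUNDS: dict[str, tuple[float, float]] = {
    "r_m": (60.0, 100.0),
    "r_a": (150.0, 400.0),
    "g_na": (7.5, 30.0),
    "g_kdr": (5.5, 22.0),
    "g_h": (0.5, 6.0),
    "g_ka": (0.05, 0.20),
    "g_cal": (1.25, 5.0),
    "g_cat": (0.125, 0.5),
    "g_can": (1.25, 5.0),
    "g_km": (0.005, 0.02),
    "g_bk": (0.4, 1.6),
    "g_sk": (0.25, 1.0),
    "totpp": (0.01, 0.5),
    "totbuf": (0.1, 2.5),
}

#: parameters describing active mechanisms (used for phenotype embeddings)
ACTIVE_PARAMS = ("g_na", "g_kdr", "g_h", "g_ka", "g_cal", "g_cat", "g_can",
                 "g_km", "g_bk", "g_sk", "totpp", "totbuf")


def sample_parameters(bounds: dict | None = None, seed: int = 0,
                      index: int | None = None) -> ParameterVector:
    """One uniform draw per parameter, reproducible per (seed, index)."""
    if bounds is None:
        bounds = TABLE1_BOUNDS
    for name, (lo, hi) in bounds.items():
        if lo > hi:
            raise ValueError(f"{name}: lower bound exceeds upper bound")
    if index is None:
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))
    draws = {
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in bounds.items()
    }
    return ParameterVector(**draws)


def validate(m: MeasurementVector, bounds: MeasurementBounds | None = None):
    """(valid flag, per-criterion flags) against inclusive bounds.

    Only the 11 validation measurements are tested; a NaN measurement
    raises, since validity is then undecidable.
    """
    if bounds is None:
        bounds = MeasurementBounds()
    flags = {}
    for name in VALIDATION_FIELDS:
        val = getattr(m, name)
        if not np.isfinite(val):
            raise ValueError(f"measurement {name} is undefined; cannot validate")
        lo, hi = bounds[name]
        flags[name] = bool(lo <= val <= hi)
    return all(flags.values()), flags


def measure_model(model, params: ParameterVector,
                  config: sim.SolverConfig | None = None,
                  settle_s: float = 5.0) -> MeasurementVector:
    """Run the full validation battery on one model.

    Protocols (all from the same settled state, after ``settle_s`` seconds
    of stimulus-free integration): 6 s quiescence for V_RMP/V_SD; -50..+50
    pA steps of 300 ms for R_in; -250 pA x 800 ms for sag; a 0-15 Hz /
    100 pA chirp over 15 s for the impedance profile; 250 pA x 1 s for the
    firing rate and AP measurements; 1 nA x 50 ms for bAP amplitudes and
    dV/dt extremes at the soma and ~150/~300 µm apical sites.
    """
    if config is None:
        config = sim.SolverConfig()
    cell = sim.compile_cell(model, params, config)
    dt_ms = cell.dt_ms

    m = MeasurementVector()
    # quiescent recording covering the settle period and the RMP window
    quiet_s = max(6.0, settle_s + 1.0)
    proto = sim.Protocol(settle_s=quiet_s, stimuli=[], record_sites=("soma",))
    traces = sim.run(model, params, proto, cell=cell)
    m.v_rmp, m.v_sd = measure_rmp_sd(
        traces["soma"], window_s=(quiet_s - 1.0, quiet_s)
    )
    settled = traces["_state"]

    def from_settled(stimuli, extra_sites=(), post_ms=0.0):
        proto = sim.Protocol(
            settle_s=0.0, stimuli=stimuli,
            record_sites=("soma",) + tuple(extra_sites), post_ms=post_ms,
        )
        return sim.run(model, params, proto, cell=cell, init_state=settled)

    # input resistance: V-I slope of steady-state responses
    amps_pA = np.arange(-50.0, 51.0, 10.0)
    v_ss = []
    for a in amps_pA:
        tr = from_settled([sim.StepStim("soma", a * 1e-3, 0.0, 300.0)])
        v = tr["soma"].samples
        n_tail = max(1, int(round(30.0 / dt_ms)))
        v_ss.append(float(np.mean(v[-n_tail:])))
    m.r_in = measure_rin(amps_pA, v_ss)

    # sag ratio under -250 pA x 800 ms
    tr = from_settled([sim.StepStim("soma", -0.25, 0.0, 800.0)])
    m.sag = measure_sag(tr["soma"], onset_s=0.0, dur_s=0.8, baseline_s=0.0)

    # impedance profile from the 0-15 Hz chirp
    chirp_pA = sim.make_chirp(100.0, 0.0, 15.0, 15.0, dt_ms * 1e-3)
    tr = from_settled([sim.WaveStim("soma", chirp_pA * 1e-3)])
    v_resp = tr["soma"].samples[1:]  # drop the pre-stimulus initial sample
    _, _, m.f_r, m.q_r, m.z_max = impedance_profile(
        (v_resp, dt_ms * 1e-3), (chirp_pA, dt_ms * 1e-3), baseline=m.v_rmp
    )

    # 250 pA x 1 s: firing rate and AP-train measurements
    tr = from_settled([sim.StepStim("soma", 0.25, 0.0, 1000.0)], post_ms=50.0)
    ap = ap_measurements(tr["soma"], m.v_rmp, onset_s=0.0, dur_s=1.0)
    m.f_250 = ap["f_250"]
    m.t_1ap = ap["t_1ap"]
    m.t_1isi = ap["t_1isi"]
    m.v_ahp = ap["v_ahp"]
    m.v_th = ap["v_th"]
    m.t_aphw = ap["t_aphw"]

    # bAP protocol: 1 nA x 50 ms, amplitudes + dV/dt extremes per site
    sites = (("apical", 150.0), ("apical", 300.0))
    tr = from_settled(
        [sim.StepStim("soma", 1.0, 0.0, 50.0)], extra_sites=sites, post_ms=20.0
    )
    amps = bap_amplitudes(
        {k: v for k, v in tr.items() if not k.startswith("_")}, onset_s=0.0
    )
    m.v_ap0 = amps["soma"]
    m.v_ap150 = amps["apical_150"]
    m.v_ap300 = amps["apical_300"]
    for tag, suff in (("soma", "0"), ("apical_150", "150"), ("apical_300", "300")):
        v = np.asarray(tr[tag].samples)
        dvdt = np.diff(v) / (tr[tag].dt * 1e3)
        setattr(m, f"dvdt_max_{suff}", float(np.max(dvdt)))
        setattr(m, f"dvdt_min_{suff}", float(np.min(dvdt)))
    return m


def run_search(model, n_models: int, seed: int = 0,
               bounds: dict | None = None,
               meas_bounds: MeasurementBounds | None = None,
               config: sim.SolverConfig | None = None,
               settle_s: float = 5.0,
               progress: bool = False) -> pd.DataFrame:
    """Generate and evaluate ``n_models`` random models; return the table.

    One row per model: sub-seed, the 14 parameters, all measurements, the
    per-criterion pass flags and the overall valid flag. Simulation
    failures (divergence) are flagged in the ``failed`` column and do not
    stop the search. Deterministic for fixed (seed, bounds, config).
    """
    if n_models < 1:
        raise ValueError("need n_models >= 1")
    if meas_bounds is None:
        meas_bounds = MeasurementBounds()
    rows = []
    for idx in range(n_models):
        params = sample_parameters(bounds, seed=seed, index=idx)
        row = {"model_id": idx, "seed": seed, **params.as_dict()}
        try:
            m = measure_model(model, params, config=config, settle_s=settle_s)
            valid, flags = validate(m, meas_bounds)
            row.update(m.as_dict())
            row.update({f"pass_{k}": v for k, v in flags.items()})
            row["valid"] = valid
            row["failed"] = False
        except (sim.SimulationDiverged, ValueError, FloatingPointError):
            row.update(MeasurementVector().as_dict())
            row.update({f"pass_{k}": False for k in VALIDATION_FIELDS})
            row["valid"] = False
            row["failed"] = True
        rows.append(row)
        if progress:
            print(f"model {idx + 1}/{n_models} "
                  f"valid={row['valid']} failed={row['failed']}", flush=True)
    return pd.DataFrame(rows)


def degeneracy_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Span of every parameter across the valid subset (min, max, range frac).

    The range fraction is the spanned fraction of the sampling bounds; a
    value near 1 with weak pairwise correlations is the signature of
    ion-channel degeneracy.
    """
    valid = table[table["valid"]] if "valid" in table else table
    recs = []
    for name, (lo, hi) in TABLE1_BOUNDS.items():
        if name not in valid or len(valid) == 0:
            continue
        vals = valid[name]
        recs.append({
            "parameter": name,
            "min": float(vals.min()),
            "max": float(vals.max()),
            "span_fraction": float((vals.max() - vals.min()) / (hi - lo)),
        })
    return pd.DataFrame(recs)
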