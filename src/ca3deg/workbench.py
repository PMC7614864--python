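"""Pipeline orchestration: configuration, staged execution, persistence.

A :class:`RunConfig` bundles everything a full run needs — morphology
source, kinetics file, sampling bounds, measurement bounds, CSB criteria,
protocol choices, seeds and output paths. :func:`run_pipeline` executes an
ordered subset of the stages

    search -> classify -> csb -> vkm -> report

persisting each stage's table as CSV next to a JSON provenance sidecar
(config digest + seed), and refusing to run a stage whose upstream
artifact is missing. Re-running with an unchanged config reuses existing
artifacts, so pipelines are resumable and byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ca3deg import simulator as sim
from ca3deg.channels import load_kinetics
from ca3deg.csb import CSB_PROTOCOLS, CSBCriteria, run_csb_protocol, score_csb_traces
from ca3deg.measurements import MeasurementBounds
from ca3deg.morphology import build_synthetic_morphology, discretize, load_swc
from ca3deg.mpmoss import ParameterVector, TABLE1_BOUNDS, run_search
from ca3deg.phenotype import classify_ib_rs
from ca3deg.synapses import place_synapses
from ca3deg.vkm import KNOCKOUT_TARGETS, run_vkm

log = logging.getLogger("ca3deg")

STAGES = ("search", "classify", "csb", "vkm", "report")

__all__ = ["RunConfig", "run_pipeline", "build_model", "STAGES"]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; YAML round-trippable."""

    # morphology
    morphology_source: str = "synthetic"  # 'synthetic' | 'swc'
    swc_path: str | None = None
    d_lambda: float = 0.1
    f_lambda: float = 100.0
    # kinetics
    kinetics_path: str | None = None  # None -> packaged defaults
    # search
    n_models: int = 200
    seed: int = 0
    param_bounds: dict = field(default_factory=lambda: dict(TABLE1_BOUNDS))
    settle_s: float = 5.0
    # protocols / scoring
    csb_protocols: tuple = ("somatic900", "synaptic5Hz")
    vkm_targets: tuple = tuple(t for t in KNOCKOUT_TARGETS)
    n_synapses: int = 100
    synapse_seed: int = 0
    # output
    out_dir: str = "ca3deg_run"

    def __post_init__(self):
        # YAML round-trips tuples as lists; normalize so configs compare
        # and digest identically
        self.csb_protocols = tuple(self.csb_protocols)
        self.vkm_targets = tuple(self.vkm_targets)
        self.param_bounds = {
            k: tuple(v) for k, v in dict(self.param_bounds).items()
        }

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def build_model(config: RunConfig):
    """Morphology + discretization from a config."""
    if config.morphology_source == "swc":
        if not config.swc_path:
            raise ValueError("morphology_source 'swc' requires swc_path")
        tree = load_swc(config.swc_path)
    elif config.morphology_source == "synthetic":
        tree = build_synthetic_morphology()
    else:
        raise ValueError(
            f"unknown morphology source {config.morphology_source!r}"
        )
    return discretize(tree, d_lambda=config.d_lambda, f=config.f_lambda)


def _solver_config(config: RunConfig) -> sim.SolverConfig:
    kin = load_kinetics(config.kinetics_path) if config.kinetics_path else None
    return sim.SolverConfig(kinetics=kin)


def _params_from_row(row) -> ParameterVector:
    return ParameterVector(
        **{k: float(row[k]) for k in ParameterVector.field_names()}
    )


def _artifact(out: Path, stage: str) -> Path:
    return out / f"{stage}.csv"


def _write_stage(out: Path, stage: str, df: pd.DataFrame,
                 config: RunConfig) -> None:
    df.to_csv(_artifact(out, stage), index=False)
    meta = {"stage": stage, "config_digest": config.digest(),
            "seed": config.seed}
    (out / f"{stage}.meta.json").write_text(json.dumps(meta, indent=1))


def _load_stage(out: Path, stage: str, config: RunConfig):
    art = _artifact(out, stage)
    meta_p = out / f"{stage}.meta.json"
    if not art.exists() or not meta_p.exists():
        return None
    meta = json.loads(meta_p.read_text())
    if meta.get("config_digest") != config.digest():
        return None
    return pd.read_csv(art)


def run_pipeline(config: RunConfig, stages=("search",)) -> dict:
    """Execute pipeline stages in order; returns ``{stage: DataFrame}``.

    Stage dependencies (classify/csb need search, vkm needs csb) are
    enforced: a missing upstream artifact raises a dependency error naming
    the stage. Completed stages with a matching config digest are reused.
    """
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    model = build_model(config)
    scfg = _solver_config(config)
    results: dict[str, pd.DataFrame] = {}

    def need(stage: str, for_stage: str) -> pd.DataFrame:
        if stage in results:
            return results[stage]
        cached = _load_stage(out, stage, config)
        if cached is None:
            raise RuntimeError(
                f"stage '{for_stage}' needs the '{stage}' artifact; "
                f"run the '{stage}' stage first"
            )
        results[stage] = cached
        return cached

    for stage in stages:
        cached = _load_stage(out, stage, config)
        if cached is not None:
            log.info("stage %s: reusing artifact (digest match)", stage)
            results[stage] = cached
            continue
        log.info("stage %s: running", stage)
        if stage == "search":
            df = run_search(model, config.n_models, seed=config.seed,
                            bounds=config.param_bounds,
                            config=scfg, settle_s=config.settle_s)
        elif stage == "classify":
            df = _classify_stage(model, need("search", stage), config, scfg)
        elif stage == "csb":
            df = _csb_stage(model, need("search", stage), config, scfg)
        elif stage == "vkm":
            df = _vkm_stage(model, need("csb", stage), need("search", stage),
                            config, scfg)
        elif stage == "report":
            for up in ("search", "classify", "csb", "vkm"):
                if up not in results:
                    cached_up = _load_stage(out, up, config)
                    if cached_up is not None:
                        results[up] = cached_up
            df = _report_stage(results, out, config)
        _write_stage(out, stage, df, config)
        results[stage] = df
    return results


def _valid_rows(pop: pd.DataFrame) -> pd.DataFrame:
    return pop[pop["valid"] & ~pop["failed"]]


def _classify_stage(model, pop, config, scfg):
    rows = []
    for _, row in _valid_rows(pop).iterrows():
        params = _params_from_row(row)
        cell = sim.compile_cell(model, params, scfg)
        state, _, _ = sim.stabilize(model, params, config.settle_s, cell=cell)
        proto = sim.Protocol(settle_s=0.0,
                             stimuli=[sim.StepStim("soma", 0.24, 0.0, 5500.0)])
        traces = sim.run(model, params, proto, cell=cell, init_state=state)
        prof = classify_ib_rs(traces["soma"], float(state.v[0]))
        rows.append({
            "model_id": int(row["model_id"]),
            "label": prof.label,
            "n_spikes": len(prof.spike_times),
            "low_count": prof.low_count,
        })
    return pd.DataFrame(rows)


def _csb_stage(model, pop, config, scfg):
    rows = []
    for _, row in _valid_rows(pop).iterrows():
        params = _params_from_row(row)
        for proto_name in config.csb_protocols:
            spec = CSB_PROTOCOLS[proto_name]
            syns = None
            if spec.kind == "synaptic":
                syns = place_synapses(model, n=config.n_synapses,
                                      seed=config.synapse_seed)
            cell = sim.compile_cell(model, params, scfg, synapses=syns)
            state, _, _ = sim.stabilize(model, params, config.settle_s,
                                        cell=cell)
            traces = run_csb_protocol(model, params, spec, synapses=syns,
                                      init_state=state, cell=cell)
            res = score_csb_traces(traces, spec, float(state.v[0]),
                                   CSBCriteria(), settle_s=0.0)
            rows.append({
                "model_id": int(row["model_id"]),
                "protocol": proto_name,
                "rate": res.rate,
                "dv_ap": res.mean_dv_ap(),
                "v_ramp": res.mean_v_ramp(),
                "csb_valid": res.rate > 0,
            })
    return pd.DataFrame(rows)


def _vkm_stage(model, csb_df, pop, config, scfg):
    frames = []
    for proto_name in config.csb_protocols:
        sub = csb_df[(csb_df["protocol"] == proto_name) & csb_df["csb_valid"]]
        targets = [t for t in config.vkm_targets
                   if t != "NMDAR" or
                   CSB_PROTOCOLS[proto_name].kind == "synaptic"]
        for _, crow in sub.iterrows():
            prow = pop[pop["model_id"] == crow["model_id"]].iloc[0]
            params = _params_from_row(prow)
            syns = None
            if CSB_PROTOCOLS[proto_name].kind == "synaptic":
                syns = place_synapses(model, n=config.n_synapses,
                                      seed=config.synapse_seed)
            df = run_vkm(model, params, targets, proto_name, synapses=syns,
                         config=scfg, settle_s=config.settle_s)
            df.insert(0, "model_id", int(crow["model_id"]))
            frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["model_id", "target", "protocol", "pct_dv_ap",
                     "pct_v_ramp", "pct_rate"]
        )
    return pd.concat(frames, ignore_index=True)


def _report_stage(results, out: Path, config: RunConfig) -> pd.DataFrame:
    recs = []
    pop = results.get("search")
    if pop is not None:
        nv = int(pop["valid"].sum())
        recs += [
            {"metric": "n_models", "value": len(pop)},
            {"metric": "n_valid", "value": nv},
            {"metric": "valid_fraction", "value": nv / len(pop)},
        ]
    cls = results.get("classify")
    if cls is not None and len(cls):
        recs += [
            {"metric": "n_ib", "value": int((cls["label"] == "IB").sum())},
            {"metric": "n_rs", "value": int((cls["label"] == "RS").sum())},
        ]
    csb_df = results.get("csb")
    if csb_df is not None and len(csb_df):
        for proto, sub in csb_df.groupby("protocol"):
            recs.append({"metric": f"csb_valid_{proto}",
                         "value": int(sub["csb_valid"].sum())})
            recs.append({"metric": f"mean_rate_{proto}",
                         "value": float(sub["rate"].mean())})
    return pd.DataFrame(recs)
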