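"""Voltage- and calcium-gated channel mechanisms and their dendritic distributions.

Ten channel types are modelled with Hodgkin-Huxley gating: fast sodium
(NaF), delayed-rectifier / A-type / M-type potassium (KDR, KA, KM), L/N/T
type calcium (CaL, CaN, CaT), calcium-activated potassium (SK, BK) and the
hyperpolarization-activated HCN channel. Sodium and potassium currents are
Ohmic (E_Na = 50 mV, E_K = -91 mV); calcium-channel currents use the
Goldman-Hodgkin-Katz (GHK) constant-field equation.

Gating kinetics are data, not code: each :class:`ChannelSpec` is loaded
from a declarative YAML kinetics file. The packaged defaults
(``kinetics/default.yaml``) are a standard CA3/CA1-style parameterization
in Boltzmann / Gaussian-time-constant form and can be replaced wholesale.

Somatodendritic distribution rules (path distance x from the soma, µm):

* NaF, KDR, CaN, CaT, SK, BK — uniform over soma and dendrites;
* CaL — perisomatic, x <= 50 µm;
* KM — perisomatic, x <= 100 µm;
* KA — proximal kinetics for x <= 100 µm, distal kinetics beyond; density
  rises linearly with distance along the apical dendrite;
* HCN — apical gradient g_h(x) = g_h_bar * (1 + 3x/100), uniform g_h_bar
  elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

FARADAY = 96485.33212  # C/mol
GAS_CONST = 8.31446  # J/(mol K)
CELSIUS = 34.0
BODY_T = 273.15 + CELSIUS  # simulations run at 34 degC

__all__ = [
    "ChannelSpec",
    "GateSpec",
    "load_kinetics",
    "default_kinetics",
    "hcn_density",
    "assign_conductances",
    "ghk_current",
    "channel_current",
    "gate_inf",
    "gate_tau",
    "FARADAY",
    "GAS_CONST",
    "BODY_T",
]

CHANNEL_NAMES = (
    "NaF", "KDR", "KA_prox", "KA_dist", "KM",
    "CaL", "CaN", "CaT", "SK", "BK", "HCN",
)


@dataclass
class GateSpec:
    """One HH gating variable: steady state and time constant laws.

    ``depends`` selects the controlling signal: ``v`` (plain voltage gate),
    ``ca`` (Hill function of submembrane calcium, constant tau) or
    ``v_ca_shift`` (voltage Boltzmann whose half-activation shifts with
    log10 of calcium, used for BK).
    """

    name: str
    power: int
    depends: str  # v | ca | v_ca_shift
    inf: dict
    tau: dict

    def __post_init__(self):
        if self.depends not in ("v", "ca", "v_ca_shift"):
            raise ValueError(f"unknown gate dependency {self.depends!r}")
        if self.power < 1:
            raise ValueError("gate power must be >= 1")


@dataclass
class ChannelSpec:
    """A channel mechanism: gates, current law, reversal/permeability."""

    name: str
    law: str  # ohmic | ghk
    ion: str  # na | k | ca | nonspecific
    gates: list[GateSpec] = field(default_factory=list)
    e_rev: float | None = None  # mV, ohmic only
    valence: int = 2  # ghk only

    def __post_init__(self):
        if self.law not in ("ohmic", "ghk"):
            raise ValueError(f"unknown current law {self.law!r}")
        if self.law == "ohmic" and self.e_rev is None:
            raise ValueError(f"{self.name}: ohmic channel needs a reversal potential")


def _boltzmann(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vhalf) / k))


def gate_inf(gate: GateSpec, v, ca=None):
    """Steady-state value of a gate; always in [0, 1]."""
    kind = gate.inf["kind"]
    if gate.depends == "ca":
        if kind != "hill":
            raise ValueError("calcium gates use a Hill steady state")
        ca = np.asarray(ca, dtype=float)
        kd, n = gate.inf["kd"], gate.inf["n"]
        cn = np.power(np.maximum(ca, 1e-12), n)
        return cn / (cn + kd**n)
    if kind != "boltzmann":
        raise ValueError(f"unknown steady-state law {kind!r}")
    vhalf = gate.inf["vhalf"]
    if gate.depends == "v_ca_shift":
        sh = gate.inf["shift_per_decade"]
        ca_ref = gate.inf["ca_ref"]
        ca = np.asarray(ca, dtype=float)
        vhalf = vhalf - sh * np.log10(np.maximum(ca, 1e-12) / ca_ref)
    return _boltzmann(v, vhalf, gate.inf["k"])


def gate_tau(gate: GateSpec, v):
    """Time constant in ms; strictly positive across [-120, +60] mV."""
    kind = gate.tau["kind"]
    v = np.asarray(v, dtype=float)
    if kind == "const":
        return np.full_like(v, float(gate.tau["value"]))
    if kind == "gauss":
        t = gate.tau
        return t["base"] + t["amp"] * np.exp(-(((v - t["vhalf"]) / t["sigma"]) ** 2))
    raise ValueError(f"unknown time-constant law {kind!r}")


def _parse_channel(name: str, raw: dict, consts: dict) -> ChannelSpec:
    gates = [
        GateSpec(
            name=g["name"],
            power=int(g["power"]),
            depends=g.get("depends", "v"),
            inf=g["inf"],
            tau=g["tau"],
        )
        for g in raw.get("gates", [])
    ]
    e_rev = raw.get("reversal")
    if isinstance(e_rev, str):
        e_rev = consts[e_rev]
    return ChannelSpec(
        name=name,
        law=raw["law"],
        ion=raw["ion"],
        gates=gates,
        e_rev=e_rev,
        valence=int(raw.get("valence", 2)),
    )


def load_kinetics(path=None) -> dict:
    """Load a kinetics file into ``{channel name: ChannelSpec}`` plus constants.

    Returns a dict with the channel specs under their names and the scalar
    constants (``e_na``, ``e_k``, ``e_h``, ``ca_perm_per_mS``,
    ``temperature_c``) under ``"_constants"``.
    """
    if path is None:
        with resources.files("ca3deg.kinetics").joinpath("default.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    consts = {k: v for k, v in raw.items() if k != "channels"}
    out = {"_constants": consts}
    for name, chraw in raw["channels"].items():
        if name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel name {name!r} in kinetics file")
        out[name] = _parse_channel(name, chraw, consts)
    missing = set(CHANNEL_NAMES) - set(out)
    if missing:
        raise ValueError(f"kinetics file missing channels: {sorted(missing)}")
    return out


@lru_cache(maxsize=1)
def default_kinetics() -> dict:
    """The packaged default kinetics (cached)."""
    return load_kinetics(None)


def hcn_density(x: float, g_bar: float) -> float:
    """HCN conductance density at apical path distance ``x`` µm.

    Linear gradient g_h(x) = g_bar * (1 + 3x/100) along the apical
    dendrite; same units as ``g_bar``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("path distance must be non-negative")
    return g_bar * (1.0 + 3.0 * x / 100.0)


def ka_density(x: float, g_bar: float) -> float:
    """A-type potassium density: linear rise with apical path distance.

    Same gradient slope as the HCN rule (3x per 100 µm).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("path distance must be non-negative")
    return g_bar * (1.0 + 3.0 * x / 100.0)


def assign_conductances(model, params, kinetics: dict | None = None) -> dict:
    """Per-compartment maximal conductance/permeability map for all channels.

    ``model`` is a :class:`~ca3deg.morphology.CompartmentalModel`, ``params``
    a :class:`~ca3deg.mpmoss.ParameterVector`. Conductances are returned in
    S/cm²; calcium channels in permeability units (cm/s), converted from
    their conductance-style search parameter by the kinetics constant
    ``ca_perm_per_mS``. The result is also stored on
    ``model.channel_density``.
    """
    if kinetics is None:
        kinetics = default_kinetics()
    ca_scale = kinetics["_constants"]["ca_perm_per_mS"]
    x = model.path_um
    apical = model.region == "apical"
    n = model.n_comp
    mS = 1e-3  # mS/cm2 -> S/cm2
    uS = 1e-6

    dens: dict[str, np.ndarray] = {}
    for name in ("NaF", "KDR", "CaT", "CaN", "SK", "BK"):
        base = {
            "NaF": params.g_na, "KDR": params.g_kdr, "CaT": params.g_cat,
            "CaN": params.g_can, "SK": params.g_sk, "BK": params.g_bk,
        }[name]
        scale = ca_scale if name in ("CaT", "CaN") else mS
        dens[name] = np.full(n, base * scale)
    # perisomatic channels (path-distance cutoffs inclusive)
    dens["CaL"] = np.where(x <= 50.0, params.g_cal * ca_scale, 0.0)
    dens["KM"] = np.where(x <= 100.0, params.g_km * mS, 0.0)
    # A-type: apical gradient, kinetics switch at 100 um
    g_ka = np.where(apical, ka_density(x, params.g_ka), params.g_ka) * mS
    dens["KA_prox"] = np.where(x <= 100.0, g_ka, 0.0)
    dens["KA_dist"] = np.where(x > 100.0, g_ka, 0.0)
    # HCN: apical gradient, uniform g_bar elsewhere (x treated as 0)
    dens["HCN"] = np.where(apical, hcn_density(x, params.g_h), params.g_h) * uS
    model.channel_density = dens
    return dens


def ghk_current(v, p, c_in, c_out, z=2, T=BODY_T):
    """GHK constant-field current density, outward positive, in mA/cm².

    ``v`` in mV, ``p`` permeability in cm/s, concentrations in mM,
    ``z`` the ion valence. Continuous at v = 0 (analytic limit
    i = 1e-3 z F P (c_in - c_out)).
    """
    if np.any(np.asarray(c_in) <= 0) or np.any(np.asarray(c_out) <= 0):
        raise ValueError("concentrations must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    v = np.asarray(v, dtype=float)
    u = z * (v * 1e-3) * FARADAY / (GAS_CONST * T)
    small = np.abs(u) < 1e-6
    us = np.where(small, 1.0, u)  # placeholder to keep the exact branch finite
    eu = np.exp(-us)
    frac = np.where(small, 1.0 + u / 2.0, us / (1.0 - eu))
    expo = np.where(small, 1.0 - u, eu)
    i = 1e-3 * z * FARADAY * p * frac * (c_in - c_out * expo)
    return i if i.shape else float(i)


def channel_current(spec: ChannelSpec, state: dict, v, ca=None, g_bar=1.0,
                    c_in=1e-4, c_out=2.0):
    """Current density (mA/cm², outward positive) at the given gate state.

    ``state`` maps gate names to values in [0, 1]; ``g_bar`` is the maximal
    conductance (S/cm², ohmic) or permeability (cm/s, GHK). For GHK
    channels ``c_in``/``c_out`` are the intra/extracellular concentrations
    of the permeant ion in mM.
    """
    open_frac = 1.0
    for g in spec.gates:
        val = np.asarray(state[g.name], dtype=float)
        if np.any(val < 0) or np.any(val > 1):
            raise ValueError(f"gate {g.name} outside [0, 1]")
        open_frac = open_frac * val**g.power
    if spec.law == "ohmic":
        return g_bar * open_frac * (np.asarray(v, dtype=float) - spec.e_rev) * 1.0
    return open_frac * ghk_current(v, g_bar, c_in, c_out, z=spec.valence)
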