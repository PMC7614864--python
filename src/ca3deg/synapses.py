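"""Colocalized AMPAR-NMDAR synapses with GHK multi-ion currents and Mg block.

Receptor currents follow the Goldman-Hodgkin-Katz convention per permeant
ion (NMDAR: Na, K, Ca with relative permeabilities 1, 1, 10.6; AMPAR: Na,
K), gated by a peak-normalized double-exponential conductance time course
s(t) and, for the NMDAR, the voltage-dependent magnesium block
MgB(v) = 1 / (1 + ([Mg]_o / 3.57) exp(-0.062 v)).

The fixed ionic composition ([Na]i/o = 18/140, [K]i/o = 140/5,
[Ca]i/o = 100 nM / 2 mM) puts both receptor reversal potentials at ~0 mV.
Synapses are placed randomly (membrane-area weighted) over the stratum
radiatum region of the apical dendrite; the default count is 100 and the
default NMDAR:AMPAR permeability ratio is 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ca3deg.channels import FARADAY, GAS_CONST, BODY_T
from ca3deg.simulator import dblexp_norm_factor

__all__ = [
    "IonComposition",
    "SynapseSpec",
    "mg_block",
    "syn_gate",
    "nmda_current",
    "ampa_current",
    "place_synapses",
    "DEFAULT_P_AMPA",
]

# default single-synapse AMPA permeability (cm^3/s); sized so one synapse
# gives a sub-millivolt somatic EPSP on the reduced morphology
DEFAULT_P_AMPA = 1.5e-12


@dataclass(frozen=True)
class IonComposition:
    """Intra/extracellular concentrations (mM) and physical constants."""

    na_i: float = 18.0
    na_o: float = 140.0
    k_i: float = 140.0
    k_o: float = 5.0
    ca_i: float = 1e-4
    ca_o: float = 2.0
    mg_o: float = 2.0
    T: float = BODY_T

    def __post_init__(self):
        for f in ("na_i", "na_o", "k_i", "k_o", "ca_i", "ca_o", "mg_o", "T"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass
class SynapseSpec:
    """One colocalized AMPAR-NMDAR synapse at a compartment.

    Permeabilities are point permeabilities in cm³/s; the NMDAR:AMPAR
    ratio (default 2) fixes ``p_nmda = ratio * p_ampa``. Time constants in
    ms: NMDA rise/decay 5/50, AMPA 2/10. Relative ionic permeabilities
    P_Na = P_K = 1, P_Ca = 10.6.
    """

    comp: int
    p_ampa: float = DEFAULT_P_AMPA
    p_nmda: float = 2.0 * DEFAULT_P_AMPA
    tau_r_ampa: float = 2.0
    tau_d_ampa: float = 10.0
    tau_r_nmda: float = 5.0
    tau_d_nmda: float = 50.0
    p_ca_rel: float = 10.6

    def __post_init__(self):
        if not self.tau_d_ampa > self.tau_r_ampa > 0:
            raise ValueError("AMPA: need tau_d > tau_r > 0")
        if not self.tau_d_nmda > self.tau_r_nmda > 0:
            raise ValueError("NMDA: need tau_d > tau_r > 0")
        if self.p_ampa < 0 or self.p_nmda < 0:
            raise ValueError("permeabilities must be non-negative")


def mg_block(v, mg_o: float = 2.0):
    """Fraction of NMDARs unblocked by magnesium at voltage ``v`` (mV).

    Strictly increasing in v, in (0, 1), asymptote 1 at depolarized
    potentials.
    """
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + (mg_o / 3.57) * np.exp(-0.062 * v))
    return out if out.shape else float(out)


def syn_gate(t, tau_r: float, tau_d: float):
    """Peak-normalized double-exponential gating s(t) in [0, 1].

    s(t) = a (exp(-t/tau_d) - exp(-t/tau_r)) with a chosen so the maximum
    (at t* = tau_r tau_d / (tau_d - tau_r) * ln(tau_d/tau_r)) is exactly 1.
    """
    if not tau_d > tau_r > 0:
        raise ValueError("need tau_d > tau_r > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    a = dblexp_norm_factor(tau_r, tau_d)
    out = a * (np.exp(-t / tau_d) - np.exp(-t / tau_r))
    return out if out.shape else float(out)


def _ghk_point(v_mV, p_cm3_s, c_in, c_out, z, T):
    """Point-source GHK current in nA (outward positive)."""
    v = np.asarray(v_mV, dtype=float)
    u = z * (v * 1e-3) * FARADAY / (GAS_CONST * T)
    small = np.abs(u) < 1e-9
    us = np.where(small, 1.0, u)
    eu = np.exp(-us)
    frac = np.where(small, 1.0, us / (1.0 - eu))
    expo = np.where(small, 1.0, eu)
    i = 1e-3 * z * FARADAY * p_cm3_s * frac * (c_in - c_out * expo) * 1e6
    return i


def nmda_current(v, t, spec: SynapseSpec, ions: IonComposition | None = None):
    """NMDAR current components (I_Na, I_K, I_Ca) in nA at time ``t`` ms.

    Each component is p_nmda * P_ion * s(t) * MgB(v) * GHK flux; the
    calcium component is what loads the local calcium pool in full
    simulations.
    """
    if ions is None:
        ions = IonComposition()
    s = syn_gate(t, spec.tau_r_nmda, spec.tau_d_nmda)
    w = spec.p_nmda * s * mg_block(v, ions.mg_o)
    i_na = w * _ghk_point(v, 1.0, ions.na_i, ions.na_o, 1, ions.T)
    i_k = w * _ghk_point(v, 1.0, ions.k_i, ions.k_o, 1, ions.T)
    i_ca = w * spec.p_ca_rel * _ghk_point(v, 1.0, ions.ca_i, ions.ca_o, 2, ions.T)
    return i_na, i_k, i_ca


def ampa_current(v, t, spec: SynapseSpec, ions: IonComposition | None = None):
    """AMPAR current components (I_Na, I_K) in nA; no Mg dependence."""
    if ions is None:
        ions = IonComposition()
    s = syn_gate(t, spec.tau_r_ampa, spec.tau_d_ampa)
    w = spec.p_ampa * s
    i_na = w * _ghk_point(v, 1.0, ions.na_i, ions.na_o, 1, ions.T)
    i_k = w * _ghk_point(v, 1.0, ions.k_i, ions.k_o, 1, ions.T)
    return i_na, i_k


def place_synapses(model, n: int = 100, region: str = "sr", seed: int = 0,
                   p_ampa: float = DEFAULT_P_AMPA, nmda_ratio: float = 2.0,
                   sr_window: tuple = (50.0, 300.0)) -> list[SynapseSpec]:
    """Place ``n`` synapses over a dendritic region, membrane-area weighted.

    ``region='sr'`` targets the stratum radiatum (apical compartments in
    the ``sr_window`` path-distance band). Sampling is reproducible for a
    given ``seed``.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    mask = model.region_mask(region, sr_window if region == "sr" else None)
    comps = np.flatnonzero(mask)
    if len(comps) == 0:
        raise ValueError(f"region {region!r} is empty on this morphology")
    w = model.area_cm2[comps]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(comps, size=n, p=w / w.sum())
    return [
        SynapseSpec(comp=int(c), p_ampa=p_ampa, p_nmda=nmda_ratio * p_ampa)
        for c in chosen
    ]
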