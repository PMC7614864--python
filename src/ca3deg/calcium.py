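"""Intracellular calcium handling: buffer, pump, radial and longitudinal diffusion.

Each compartment carries four equal-thickness concentric annuli (shells).
Membrane calcium current loads the outermost shell; calcium, free buffer
and bound buffer diffuse radially across shell interfaces (Fick's law) and
longitudinally between corresponding shells of connected compartments. A
mobile buffer binds calcium by mass action and a membrane pump extrudes
calcium from the outer shell with Michaelis-Menten kinetics, balanced so
that the resting concentration (100 nM) is a fixed point.

The reaction and pump sub-steps are solved per shell with a linearized
backward-Euler update in closed (quadratic) form, which conserves mass
exactly and is unconditionally stable; diffusion is explicit, stable at
the 25 µs step for the compartment sizes used here.

This module is the plain-NumPy reference used by the tests; the simulator's
jitted kernel implements the same update and is cross-checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ca3deg.channels import FARADAY

CA_REST = 1e-4  # mM (100 nM resting free calcium)

__all__ = ["CalciumConfig", "CalciumState", "init_calcium", "step_calcium",
           "shell_geometry", "CA_REST"]


@dataclass
class CalciumConfig:
    """Calcium-handling constants.

    totbuf (mM) and totpp (dimensionless density scale) are the two search
    parameters; the kinetic constants are package defaults exposed here.
    ``pump_vmax_unit`` converts totpp into the maximal pump flux per
    membrane area (mM·µm/ms per unit totpp).
    """

    totbuf: float = 1.2  # mM total buffer
    totpp: float = 0.2  # pump density scale
    k_on: float = 10.0  # /mM/ms buffer forward rate
    k_off: float = 0.01  # /ms buffer backward rate
    d_ca: float = 0.22  # um^2/ms calcium diffusion
    d_buf: float = 0.05  # um^2/ms buffer diffusion
    pump_km: float = 5e-4  # mM pump Michaelis constant
    pump_vmax_unit: float = 0.1  # mM*um/ms per unit totpp
    ca_rest: float = CA_REST


@dataclass
class CalciumState:
    """Per-compartment, per-shell concentrations (mM); shell 0 is outermost."""

    ca: np.ndarray  # (n_comp, 4) free calcium
    buf: np.ndarray  # (n_comp, 4) free buffer
    bound: np.ndarray  # (n_comp, 4) calcium-bound buffer

    def copy(self) -> "CalciumState":
        return CalciumState(self.ca.copy(), self.buf.copy(), self.bound.copy())

    def total_calcium_mol(self, geom) -> float:
        """Total calcium (free + bound) in arbitrary mol units (conc x volume)."""
        vol = geom["shell_vol"]
        return float(np.sum((self.ca + self.bound) * vol))


def shell_geometry(model) -> dict:
    """Four equal-thickness shells per compartment.

    Returns per-compartment arrays: shell volumes (µm³), interface areas
    (µm²) between adjacent shells, shell thickness (µm), outer membrane
    area (µm²), and longitudinal cross-section areas (µm²) per shell.
    """
    r = model.diam / 2.0  # um
    L = model.length
    n = model.n_comp
    edges = np.stack([r * (4 - j) / 4.0 for j in range(5)], axis=1)  # (n,5) outer->0
    shell_vol = np.pi * (edges[:, :4] ** 2 - edges[:, 1:] ** 2) * L[:, None]
    iface_area = 2.0 * np.pi * edges[:, 1:4] * L[:, None]  # between shell j and j+1
    thickness = (r / 4.0)[:, None] * np.ones((n, 4))
    mem_area = 2.0 * np.pi * r * L  # lateral membrane, um^2
    cross_area = np.pi * (edges[:, :4] ** 2 - edges[:, 1:] ** 2)  # (n,4) um^2
    return {
        "shell_vol": shell_vol,
        "iface_area": iface_area,
        "thickness": thickness,
        "mem_area": mem_area,
        "cross_area": cross_area,
    }


def init_calcium(model, config: CalciumConfig | None = None) -> CalciumState:
    """Resting calcium state: 100 nM free calcium, buffer at binding equilibrium."""
    if config is None:
        config = CalciumConfig()
    n = model.n_comp
    ca = np.full((n, 4), config.ca_rest)
    kd = config.k_off / config.k_on
    bound_frac = config.ca_rest / (config.ca_rest + kd)
    bound = np.full((n, 4), config.totbuf * bound_frac)
    buf = np.full((n, 4), config.totbuf) - bound
    return CalciumState(ca=ca, buf=buf, bound=bound)


def _reaction_be(ca, buf, bound, k_on, k_off, dt):
    """Backward-Euler mass-action binding, closed-form quadratic root.

    Conserves ca+bound and buf+bound exactly per shell.
    """
    c_t = ca + bound
    b_t = buf + bound
    alpha = k_on * dt
    beta = 1.0 + dt * k_off + alpha * (c_t + b_t)
    gamma = bound + alpha * c_t * b_t
    disc = beta * beta - 4.0 * alpha * gamma
    x_new = (beta - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * alpha)
    x_new = np.clip(x_new, 0.0, np.minimum(c_t, b_t))
    return c_t - x_new, b_t - x_new, x_new


def _pump_be(ca, a_eff, km, ca_rest, dt):
    """Semi-implicit Michaelis-Menten pump balanced at rest.

    dca/dt = -a_eff * (ca/(ca+km) - r0) with r0 = rest occupancy; backward
    Euler in ca solved in closed form (positive quadratic root).
    """
    r0 = ca_rest / (ca_rest + km)
    b = km - ca + dt * a_eff * (1.0 - r0)
    c = -(ca * km + dt * a_eff * r0 * km)
    ca_new = (-b + np.sqrt(b * b - 4.0 * c)) / 2.0
    return np.maximum(ca_new, 0.0)


def step_calcium(
    state: CalciumState,
    model,
    i_ca_membrane: np.ndarray,
    dt_ms: float,
    config: CalciumConfig | None = None,
    geom: dict | None = None,
    pump_on: bool = True,
) -> CalciumState:
    """Advance the calcium system one step of ``dt_ms`` (<= 0.025 ms).

    ``i_ca_membrane`` is the per-compartment calcium current density in
    mA/cm² (outward positive; inward current loads the outer shell).
    Raises on a negative concentration after the step, which signals an
    unstable step size.
    """
    if dt_ms > 0.025 + 1e-12:
        raise ValueError("dt must be <= 25 us")
    if config is None:
        config = CalciumConfig()
    if geom is None:
        geom = shell_geometry(model)

    ca = state.ca.copy()
    buf = state.buf.copy()
    bound = state.bound.copy()
    vol = geom["shell_vol"]
    th = geom["thickness"]

    # membrane influx into outer shell: dC (mM/ms) = -i * 1e4 / (z F th_um)
    influx = -np.asarray(i_ca_membrane) * 1e4 / (2.0 * FARADAY * th[:, 0])
    ca[:, 0] += dt_ms * influx

    # radial diffusion (explicit, conservative)
    for arr, d in ((ca, config.d_ca), (buf, config.d_buf), (bound, config.d_buf)):
        flux = (
            d
            * geom["iface_area"]
            * (arr[:, 1:] - arr[:, :3])
            / (0.5 * (th[:, 1:] + th[:, :3]))
        )  # um^3 mM / ms, from shell j+1 into shell j
        darr = np.zeros_like(arr)
        darr[:, :3] += flux / vol[:, :3]
        darr[:, 1:] -= flux / vol[:, 1:]
        arr += dt_ms * darr

    # longitudinal diffusion between corresponding shells of coupled compartments
    parent = model.parent
    if model.n_comp > 1:
        dx = 0.5 * (model.length[1:] + model.length[parent[1:]])
        for arr, d in ((ca, config.d_ca), (buf, config.d_buf), (bound, config.d_buf)):
            a_ij = np.minimum(
                geom["cross_area"][1:], geom["cross_area"][parent[1:]]
            )
            flux = d * a_ij * (arr[parent[1:]] - arr[1:]) / dx[:, None]
            darr = np.zeros_like(arr)
            np.add.at(darr, np.arange(1, model.n_comp), flux / vol[1:])
            np.subtract.at(darr, parent[1:], flux / vol[parent[1:]])
            arr += dt_ms * darr

    # buffer binding (implicit quadratic, exact conservation)
    ca, buf, bound = _reaction_be(ca, buf, bound, config.k_on, config.k_off, dt_ms)

    # pump extrusion from outer shell, balanced at rest
    if pump_on and config.totpp > 0:
        a_eff = config.totpp * config.pump_vmax_unit / th[:, 0]  # mM/ms scale
        ca[:, 0] = _pump_be(ca[:, 0], a_eff, config.pump_km, config.ca_rest, dt_ms)

    if np.any(ca < 0) or np.any(buf < 0) or np.any(bound < 0):
        raise FloatingPointError(
            "negative concentration after calcium step (dt too large)"
        )
    return CalciumState(ca=ca, buf=buf, bound=bound)
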