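"""Jitted integration kernel for the branched-cable + gating + calcium system.

One backward-Euler step of the voltage system is solved directly on the
Hines-ordered tree (parents precede children, so a single up/down sweep
factorizes the symmetric branched tridiagonal system). Gates advance by
exponential Euler against voltage-indexed lookup tables; GHK currents are
linear in the internal concentration, i = P (A(v) c_in - B(v) c_out), so
the voltage-dependent factors A and B are tabulated once per valence.
Calcium (4 shells/compartment) uses explicit diffusion plus closed-form
implicit updates for buffering and pump extrusion.

Everything is float64 and free of ordering ambiguity, so repeated runs are
bit-identical.

Units: mV, ms, nA, µS, nF, mM, µm; channel densities S/cm² (ohmic) or
cm/s (GHK); membrane current densities mA/cm².
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ca3deg.channels import FARADAY, GAS_CONST, BODY_T

# voltage lookup-table grid
VMIN = -150.0
VMAX = 100.0
DV = 0.05
NV = int(round((VMAX - VMIN) / DV)) + 1

# fixed synaptic ionic composition (mM)
NAI, NAO = 18.0, 140.0
KI, KO = 140.0, 5.0
CAI, CAO = 1e-4, 2.0
MGO = 2.0
PCA_REL = 10.6

STATUS_OK = 0
STATUS_DIVERGED = 1


def vgrid() -> np.ndarray:
    return VMIN + DV * np.arange(NV)


def ghk_tables(z: int, T: float = BODY_T):
    """Tabulate A(v), B(v) with i[mA/cm²] = P[cm/s] (A c_in - B c_out)."""
    v = vgrid()
    u = z * (v * 1e-3) * FARADAY / (GAS_CONST * T)
    small = np.abs(u) < 1e-9
    us = np.where(small, 1.0, u)
    eu = np.exp(-us)
    frac = np.where(small, 1.0, us / (1.0 - eu))
    A = 1e-3 * z * FARADAY * frac
    B = A * np.where(small, 1.0, eu)
    return A, B


@njit(cache=True)
def _lerp(tab, pos):
    i0 = int(pos)
    fr = pos - i0
    return tab[i0] * (1.0 - fr) + tab[i0 + 1] * fr


@njit(cache=True)
def _slope(tab, pos):
    i0 = int(pos)
    return (tab[i0 + 1] - tab[i0]) / DV


@njit(cache=True)
def _vpos(v):
    pos = (v - VMIN) / DV
    if pos < 0.0:
        pos = 0.0
    elif pos > NV - 2:
        pos = float(NV - 2)
    return pos


@njit(cache=True, fastmath=True)
def integrate(
    # topology / passive (per compartment)
    parent,        # int64[n], parent[0] = -1, Hines order
    g_ax,          # f8[n] axial coupling to parent, uS
    c_nF,          # f8[n] membrane capacitance, nF
    area6,         # f8[n] membrane area * 1e6 (cm2 -> converts mA/cm2 to nA)
    g_leak_uS,     # f8[n]
    e_leak,        # f8
    # channels
    chan_law,      # int64[nc] 0 ohmic, 1 ghk(ca)
    chan_erev,     # f8[nc]
    gbar,          # f8[nc, n] S/cm2 or cm/s
    # gate instances
    gate_chan,     # int64[ng]
    gate_power,    # int64[ng]
    gate_kind,     # int64[ng] 0 v-table, 1 ca-hill, 2 v-boltzmann ca-shifted
    inf_tab,       # f8[ng, NV]
    etau_tab,      # f8[ng, NV] exp(-dt/tau(v))
    gate_p1,       # f8[ng] hill kd | bk vhalf
    gate_p2,       # f8[ng] hill n  | bk k
    gate_p3,       # f8[ng] bk shift/decade
    gate_p4,       # f8[ng] bk ca_ref
    gate_etau_c,   # f8[ng] exp(-dt/tau) for const-tau ca gates
    # GHK tables (valence 2 and 1)
    tabA2, tabB2, tabA1, tabB1,
    # calcium geometry / config
    shell_vol,     # f8[n,4] um3
    rad_geo,       # f8[n,3] iface_area/dr, um2/um -> um
    lon_geo,       # f8[n,4] min cross area / dx (0 for root), um
    th0,           # f8[n] outer shell thickness, um
    d_ca, d_buf, k_on, k_off,
    pump_a,        # f8[n] totpp*vmax_unit/th0, mM/ms
    pump_km, ca_rest,
    # synapses (aggregated per compartment)
    syn_pA,        # f8[n] summed AMPA permeability, cm3/s
    syn_pN,        # f8[n] summed NMDA permeability, cm3/s
    ev_steps,      # int64[ne] step indices of presynaptic events (sorted)
    tau_rA, tau_dA, tau_rN, tau_dN,  # ms
    norm_A, norm_N,                   # double-exp normalization factors
    # stimulation
    inj_comp,      # int64[ni]
    inj_wave,      # f8[ni, n_steps] nA
    # run control
    dt,            # ms
    n_steps,
    rec_stride,
    ca_every,      # calcium operator substep: update every k-th step
    rec_v_comp,    # int64[nrv]
    rec_ca_comp,   # int64[nrc]
    # state (modified in place)
    v, gates, ca, buf, bound,
    syn_state,     # f8[4]: ArA, AdA, ArN, AdN (rise/decay kernel states)
):
    n = parent.shape[0]
    nc = chan_law.shape[0]
    ng = gate_chan.shape[0]
    n_samp = n_steps // rec_stride + 1
    rec_v = np.empty((rec_v_comp.shape[0], n_samp))
    rec_ca = np.empty((rec_ca_comp.shape[0], n_samp))
    for k in range(rec_v_comp.shape[0]):
        rec_v[k, 0] = v[rec_v_comp[k]]
    for k in range(rec_ca_comp.shape[0]):
        rec_ca[k, 0] = ca[rec_ca_comp[k], 0]

    diag = np.empty(n)
    rhs = np.empty(n)
    cdt = c_nF / dt
    acc_flux = np.zeros(n)
    dtc = dt * ca_every
    chan_open = np.empty(nc)
    capo = np.empty(n)
    syn_capo = np.empty(n)
    posn = np.empty(n)
    i_ca = np.empty(n)
    dca = np.empty((n, 4))

    eA_r = np.exp(-dt / tau_rA)
    eA_d = np.exp(-dt / tau_dA)
    eN_r = np.exp(-dt / tau_rN)
    eN_d = np.exp(-dt / tau_dN)

    ev_ptr = 0
    status = STATUS_OK
    fail_step = -1

    for step in range(n_steps):
        # presynaptic events (synchronous across synapses)
        while ev_ptr < ev_steps.shape[0] and ev_steps[ev_ptr] == step:
            syn_state[0] += 1.0
            syn_state[1] += 1.0
            syn_state[2] += 1.0
            syn_state[3] += 1.0
            ev_ptr += 1
        sA = norm_A * (syn_state[1] - syn_state[0])
        sN = norm_N * (syn_state[3] - syn_state[2])

        # ---- assemble linearized system ----
        for i in range(n):
            vi = v[i]
            pos = _vpos(vi)
            diag[i] = cdt[i] + g_leak_uS[i]
            rhs[i] = cdt[i] * vi + g_leak_uS[i] * e_leak
            for c in range(nc):
                chan_open[c] = 1.0
            for g in range(ng):
                m = gates[g, i]
                p = gate_power[g]
                acc = m
                for _ in range(p - 1):
                    acc *= m
                chan_open[gate_chan[g]] *= acc
            po = 0.0
            for c in range(nc):
                gb = gbar[c, i]
                if gb == 0.0:
                    continue
                if chan_law[c] == 0:
                    G = gb * chan_open[c] * area6[i]
                    diag[i] += G
                    rhs[i] += G * chan_erev[c]
                else:
                    po += gb * chan_open[c]
            capo[i] = po
            if po > 0.0:
                ci = ca[i, 0]
                A = _lerp(tabA2, pos)
                B = _lerp(tabB2, pos)
                dA = _slope(tabA2, pos)
                dB = _slope(tabB2, pos)
                i_nA = po * (A * ci - B * CAO) * area6[i]
                g_uS = po * (dA * ci - dB * CAO) * area6[i]
                diag[i] += g_uS
                rhs[i] += g_uS * vi - i_nA
            # synapses aggregated on this compartment
            syn_capo[i] = 0.0
            if (syn_pA[i] > 0.0 and sA > 1e-12) or (syn_pN[i] > 0.0 and sN > 1e-12):
                mgb = 1.0 / (1.0 + (MGO / 3.57) * np.exp(-0.062 * vi))
                A1 = _lerp(tabA1, pos)
                B1 = _lerp(tabB1, pos)
                dA1 = _slope(tabA1, pos)
                dB1 = _slope(tabB1, pos)
                fNaK = (A1 * NAI - B1 * NAO) + (A1 * KI - B1 * KO)
                dfNaK = (dA1 * NAI - dB1 * NAO) + (dA1 * KI - dB1 * KO)
                A2 = _lerp(tabA2, pos)
                B2 = _lerp(tabB2, pos)
                dA2 = _slope(tabA2, pos)
                dB2 = _slope(tabB2, pos)
                fCa = PCA_REL * (A2 * CAI - B2 * CAO)
                dfCa = PCA_REL * (dA2 * CAI - dB2 * CAO)
                wA = syn_pA[i] * sA
                wN = syn_pN[i] * sN * mgb
                i_nA = (wA * fNaK + wN * (fNaK + fCa)) * 1e6
                g_uS = (wA * dfNaK + wN * (dfNaK + dfCa)) * 1e6
                diag[i] += g_uS
                rhs[i] += g_uS * vi - i_nA
                syn_capo[i] = wN * PCA_REL

        for k in range(inj_comp.shape[0]):
            rhs[inj_comp[k]] += inj_wave[k, step]

        for i in range(1, n):
            diag[i] += g_ax[i]
            diag[parent[i]] += g_ax[i]

        # ---- Hines solve ----
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / diag[i]
            diag[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]

        # ---- calcium membrane flux at the new voltage (accumulated) ----
        for i in range(n):
            posn[i] = _vpos(v[i])
        for i in range(n):
            pos = posn[i]
            A2 = _lerp(tabA2, pos)
            B2 = _lerp(tabB2, pos)
            i_ca[i] = capo[i] * (A2 * ca[i, 0] - B2 * CAO)  # mA/cm2
            flux = -i_ca[i] * 1e4 / (2.0 * FARADAY * th0[i])  # mM/ms
            if syn_capo[i] > 0.0:
                i_syn_ca_nA = syn_capo[i] * (A2 * CAI - B2 * CAO) * 1e6
                flux += -i_syn_ca_nA * 1e6 / (2.0 * FARADAY * shell_vol[i, 0])
            acc_flux[i] += flux

        # ---- calcium sub-step: diffusion, buffering, pump ----
        # calcium time scales are slow relative to dt, so the expensive
        # transport/reaction update runs every ca_every-th step at
        # dt * ca_every with the averaged membrane influx
        if (step + 1) % ca_every == 0:
            for i in range(n):
                dca[i, 0] = acc_flux[i] / ca_every
                acc_flux[i] = 0.0
                dca[i, 1] = 0.0
                dca[i, 2] = 0.0
                dca[i, 3] = 0.0

            # radial diffusion (explicit)
            for i in range(n):
                for j in range(3):
                    fl_ca = d_ca * rad_geo[i, j] * (ca[i, j + 1] - ca[i, j])
                    dca[i, j] += fl_ca / shell_vol[i, j]
                    dca[i, j + 1] -= fl_ca / shell_vol[i, j + 1]
            # longitudinal diffusion of calcium between matching shells
            for i in range(1, n):
                p = parent[i]
                for j in range(4):
                    fl = d_ca * lon_geo[i, j] * (ca[p, j] - ca[i, j])
                    dca[i, j] += fl / shell_vol[i, j]
                    dca[p, j] -= fl / shell_vol[p, j]
            for i in range(n):
                for j in range(4):
                    ca[i, j] += dtc * dca[i, j]

            # buffer diffusion (radial + longitudinal), both species
            for i in range(n):
                for j in range(3):
                    flb = d_buf * rad_geo[i, j] * (buf[i, j + 1] - buf[i, j])
                    flx = d_buf * rad_geo[i, j] * (bound[i, j + 1] - bound[i, j])
                    buf[i, j] += dtc * flb / shell_vol[i, j]
                    buf[i, j + 1] -= dtc * flb / shell_vol[i, j + 1]
                    bound[i, j] += dtc * flx / shell_vol[i, j]
                    bound[i, j + 1] -= dtc * flx / shell_vol[i, j + 1]
            for i in range(1, n):
                p = parent[i]
                for j in range(4):
                    flb = d_buf * lon_geo[i, j] * (buf[p, j] - buf[i, j])
                    flx = d_buf * lon_geo[i, j] * (bound[p, j] - bound[i, j])
                    buf[i, j] += dtc * flb / shell_vol[i, j]
                    buf[p, j] -= dtc * flb / shell_vol[p, j]
                    bound[i, j] += dtc * flx / shell_vol[i, j]
                    bound[p, j] -= dtc * flx / shell_vol[p, j]

            # mass-action buffering: implicit closed-form quadratic
            for i in range(n):
                for j in range(4):
                    c_t = ca[i, j] + bound[i, j]
                    b_t = buf[i, j] + bound[i, j]
                    alpha = k_on * dtc
                    beta = 1.0 + dtc * k_off + alpha * (c_t + b_t)
                    gamma = bound[i, j] + alpha * c_t * b_t
                    disc = beta * beta - 4.0 * alpha * gamma
                    if disc < 0.0:
                        disc = 0.0
                    x_new = (beta - np.sqrt(disc)) / (2.0 * alpha)
                    lim = c_t if c_t < b_t else b_t
                    if x_new < 0.0:
                        x_new = 0.0
                    elif x_new > lim:
                        x_new = lim
                    ca[i, j] = c_t - x_new
                    buf[i, j] = b_t - x_new
                    bound[i, j] = x_new

            # pump extrusion from the outer shell (rest-balanced, implicit)
            for i in range(n):
                if pump_a[i] > 0.0:
                    c0 = ca[i, 0]
                    r0 = ca_rest / (ca_rest + pump_km)
                    b = pump_km - c0 + dtc * pump_a[i] * (1.0 - r0)
                    cq = -(c0 * pump_km + dtc * pump_a[i] * r0 * pump_km)
                    cn = (-b + np.sqrt(b * b - 4.0 * cq)) / 2.0
                    ca[i, 0] = cn if cn > 0.0 else 0.0

        # ---- gate update (exponential Euler at the new voltage) ----
        for g in range(ng):
            kind = gate_kind[g]
            if kind == 0:
                for i in range(n):
                    inf = _lerp(inf_tab[g], posn[i])
                    et = _lerp(etau_tab[g], posn[i])
                    gates[g, i] = inf + (gates[g, i] - inf) * et
            elif kind == 1:
                kd = gate_p1[g]
                hn = gate_p2[g]
                hni = int(hn)
                et = gate_etau_c[g]
                use_int = abs(hn - hni) < 1e-9
                for i in range(n):
                    cc = ca[i, 0]
                    if cc < 1e-12:
                        cc = 1e-12
                    r = cc / kd
                    if use_int:
                        rn = 1.0
                        for _ in range(hni):
                            rn *= r
                    else:
                        rn = r**hn
                    inf = rn / (rn + 1.0)
                    gates[g, i] = inf + (gates[g, i] - inf) * et
            else:
                vh0 = gate_p1[g]
                kk = gate_p2[g]
                # shift in ln units: vhalf - sh*log10(ca/ref)
                shl = gate_p3[g] * 0.43429448190325176
                caref = gate_p4[g]
                et = gate_etau_c[g]
                for i in range(n):
                    cc = ca[i, 0]
                    if cc < 1e-12:
                        cc = 1e-12
                    vh = vh0 - shl * np.log(cc / caref)
                    inf = 1.0 / (1.0 + np.exp(-(v[i] - vh) / kk))
                    gates[g, i] = inf + (gates[g, i] - inf) * et

        # decay synaptic kernel states
        syn_state[0] *= eA_r
        syn_state[1] *= eA_d
        syn_state[2] *= eN_r
        syn_state[3] *= eN_d

        # ---- record / divergence check ----
        if (step + 1) % rec_stride == 0:
            k = (step + 1) // rec_stride
            ok = True
            for i in range(n):
                if not np.isfinite(v[i]) or v[i] < VMIN or v[i] > VMAX:
                    ok = False
                    break
            if not ok:
                status = STATUS_DIVERGED
                fail_step = step
                for kk2 in range(rec_v_comp.shape[0]):
                    rec_v[kk2, k:] = np.nan
                for kk2 in range(rec_ca_comp.shape[0]):
                    rec_ca[kk2, k:] = np.nan
                break
            for kk2 in range(rec_v_comp.shape[0]):
                rec_v[kk2, k] = v[rec_v_comp[kk2]]
            for kk2 in range(rec_ca_comp.shape[0]):
                rec_ca[kk2, k] = ca[rec_ca_comp[kk2], 0]

    return rec_v, rec_ca, status, fail_step
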