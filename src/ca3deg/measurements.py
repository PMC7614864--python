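"""Electrophysiological measurements from recorded traces.

Implements the 11 validation measurements used to accept models into the
population (resting potential and its stability, input resistance, sag
ratio, impedance resonance frequency/strength/peak, firing rate at 250 pA,
and back-propagating AP amplitudes at the soma and ~150/~300 µm dendritic
sites) plus the 11 action-potential measurements computed on validated
models (first-spike latency, first ISI, AHP depth, AP half-width,
threshold, and dV/dt extremes at three somatodendritic sites).

Spike criterion: an upward crossing of -20 mV whose following peak reaches
at least 0 mV, with 1 ms refractory separation. The threshold criterion is
robust to the within-burst amplitude decrements of complex spike bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "MeasurementVector",
    "MeasurementBounds",
    "VALIDATION_FIELDS",
    "detect_spikes",
    "measure_rmp_sd",
    "measure_rin",
    "measure_sag",
    "impedance_profile",
    "ap_measurements",
    "bap_amplitudes",
]

SPIKE_THRESH = -20.0  # mV upward crossing
SPIKE_PEAK_MIN = 0.0  # mV minimum peak
SPIKE_REFRACT = 1.0e-3  # s

#: the 11 measurements validated against electrophysiological bounds
VALIDATION_FIELDS = (
    "v_rmp", "v_sd", "r_in", "sag", "f_r", "q_r", "z_max",
    "f_250", "v_ap0", "v_ap150", "v_ap300",
)


@dataclass
class MeasurementVector:
    """All intrinsic measurements of one model; NaN marks 'undefined'.

    Units: mV for potentials (``v_sd`` in µV), MΩ for resistances/impedance,
    Hz for frequencies, ms for times, V/s for voltage derivatives.
    """

    v_rmp: float = np.nan
    v_sd: float = np.nan  # uV
    r_in: float = np.nan
    sag: float = np.nan
    f_r: float = np.nan
    q_r: float = np.nan
    z_max: float = np.nan
    f_250: float = np.nan
    v_ap0: float = np.nan
    v_ap150: float = np.nan
    v_ap300: float = np.nan
    # AP measurements (computed on validated models)
    t_1ap: float = np.nan
    t_1isi: float = np.nan
    v_ahp: float = np.nan
    t_aphw: float = np.nan
    v_th: float = np.nan
    dvdt_max_0: float = np.nan
    dvdt_min_0: float = np.nan
    dvdt_max_150: float = np.nan
    dvdt_min_150: float = np.nan
    dvdt_max_300: float = np.nan
    dvdt_min_300: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_TABLE2_DEFAULTS = {
    "v_rmp": (-70.0, -60.0),
    "v_sd": (0.0, 0.01),  # uV; doubles as a numerical-stability check
    "r_in": (60.0, 150.0),
    "sag": (0.94, 1.0),
    "f_r": (1.0, 1.76),
    "q_r": (1.0, 1.1),
    "z_max": (65.0, 150.0),
    "f_250": (4.0, 10.0),
    "v_ap0": (90.0, 110.0),
    "v_ap150": (70.0, 90.0),
    "v_ap300": (60.0, 80.0),
}


@dataclass
class MeasurementBounds:
    """Per-measurement [lower, upper] electrophysiological bounds."""

    bounds: dict = None

    def __post_init__(self):
        if self.bounds is None:
            self.bounds = dict(_TABLE2_DEFAULTS)
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")

    def __getitem__(self, name):
        return self.bounds[name]

    def names(self):
        return tuple(self.bounds)


def _trace_arrays(trace):
    """Accept a Trace or (samples, dt_s) pair."""
    if hasattr(trace, "samples"):
        return np.asarray(trace.samples, dtype=float), float(trace.dt)
    v, dt = trace
    return np.asarray(v, dtype=float), float(dt)


def detect_spikes(trace, thresh: float = SPIKE_THRESH,
                  peak_min: float = SPIKE_PEAK_MIN,
                  refract_s: float = SPIKE_REFRACT):
    """Spike times (s, at the peak sample) and peak values (mV).

    A spike is an upward crossing of ``thresh`` whose subsequent local
    maximum (before the trace falls back below threshold) reaches
    ``peak_min``; successive spikes are at least ``refract_s`` apart.
    """
    v, dt = _trace_arrays(trace)
    if len(v) < 3:
        return np.array([]), np.array([])
    above = v >= thresh
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times, peaks = [], []
    last_t = -np.inf
    for c in crossings:
        end = c
        while end < len(v) and v[end] >= thresh:
            end += 1
        seg = v[c:end]
        if len(seg) == 0:
            continue
        pk_rel = int(np.argmax(seg))
        pk_val = seg[pk_rel]
        if pk_val < peak_min:
            continue
        t = (c + pk_rel) * dt
        if t - last_t < refract_s:
            continue
        times.append(t)
        peaks.append(pk_val)
        last_t = t
    return np.asarray(times), np.asarray(peaks)


def measure_rmp_sd(trace, window_s=(5.0, 6.0)):
    """Resting potential (mV) and its SD (µV) over the quiescent window."""
    v, dt = _trace_arrays(trace)
    i0 = int(round(window_s[0] / dt))
    i1 = int(round(window_s[1] / dt))
    if i1 > len(v):
        raise ValueError(
            f"trace too short for the {window_s} s window ({len(v) * dt:.3f} s)"
        )
    seg = v[i0:i1]
    return float(np.mean(seg)), float(np.std(seg) * 1e3)


def measure_rin(currents_pA, v_ss_mV) -> float:
    """Input resistance (MΩ): least-squares slope of the V-I relation.

    ``currents_pA`` and ``v_ss_mV`` are matched arrays of injected current
    and steady-state voltage response.
    """
    i = np.asarray(currents_pA, dtype=float)
    v = np.asarray(v_ss_mV, dtype=float)
    if len(i) < 2 or len(i) != len(v):
        raise ValueError("need >= 2 matched (I, V) points")
    if np.ptp(i) == 0:
        raise ValueError("all currents identical: V-I fit is singular")
    slope = np.polyfit(i, v, 1)[0]  # mV/pA = GOhm
    return float(slope * 1e3)  # MOhm


def measure_sag(trace, onset_s: float, dur_s: float = 0.8,
                baseline_s: float = 0.05) -> float:
    """Sag ratio: steady-state / peak voltage deflection under the pulse.

    Deflections are measured from the pre-pulse baseline (mean over
    ``baseline_s`` before onset); the steady state is the mean over the
    last 10% of the pulse.
    """
    v, dt = _trace_arrays(trace)
    i_on = int(round(onset_s / dt))
    i_off = int(round((onset_s + dur_s) / dt))
    ib = max(0, i_on - int(round(baseline_s / dt)))
    base = float(np.mean(v[ib:i_on])) if i_on > ib else float(v[i_on])
    pulse = v[i_on:i_off]
    if len(pulse) == 0:
        raise ValueError("pulse window empty")
    v_max_defl = base - float(np.min(pulse))  # hyperpolarizing pulse
    tail = pulse[-max(1, len(pulse) // 10):]
    v_ss_defl = base - float(np.mean(tail))
    if v_max_defl <= 0:
        raise ValueError("no hyperpolarizing deflection in the pulse window")
    return v_ss_defl / v_max_defl


def impedance_profile(v_trace, i_trace, f_max: float = 15.0,
                      f_min: float = 0.5, f_qr: float = 0.5,
                      baseline: float | None = None, smooth_bins: int = 5):
    """Impedance amplitude profile from chirp response.

    |Z(f)| = |FFT(v) / FFT(i)| over [f_min, f_max] Hz with ``v`` in mV and
    ``i`` in pA (|Z| then lands in GΩ and is converted to MΩ). The lower
    band edge (default 0.5 Hz, the Q_R reference frequency) excludes bins
    below the chirp's spectral support. Returns
    ``(freqs, z_mag_MOhm, f_r, q_r, z_max)`` with the resonance frequency
    f_r at the profile maximum and Q_R = |Z(f_r)| / |Z(f_qr)|.
    """
    v, dt = _trace_arrays(v_trace)
    i, dt_i = _trace_arrays(i_trace)
    if len(v) != len(i) or abs(dt - dt_i) > 1e-12:
        raise ValueError("voltage and current traces must share sampling")
    if baseline is None:
        baseline = v[0]
    # end-only cosine taper: the record starts smoothly at rest, but the
    # abrupt stop at the top of the sweep leaks into the lowest bins and
    # biases the argmax of weakly resonant profiles; a leading taper
    # would instead distort the slow early cycles that carry all the
    # low-frequency energy
    n = len(v)
    w = np.ones(n)
    m = max(2, int(0.05 * n))
    w[-m:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(m) / m))
    vf = np.fft.rfft((v - baseline) * w)
    cf = np.fft.rfft(i * w)
    freqs = np.fft.rfftfreq(len(v), dt)
    band = (freqs >= min(f_min, f_qr)) & (freqs <= f_max)
    if not band.any():
        raise ValueError("no frequency bins in the requested band")
    mag_i = np.abs(cf[band])
    if np.any(mag_i < 1e-12 * np.max(np.abs(cf))):
        raise ZeroDivisionError("chirp spectrum vanishes inside the band")
    z = np.abs(vf[band]) / mag_i * 1e3  # mV/pA = GOhm -> MOhm
    fb = freqs[band]
    zs = z
    if smooth_bins > 1:
        # edge-corrected moving average, used for the scalar estimates
        # only: damps per-bin FFT ripple, which otherwise dominates the
        # argmax of near-flat (weakly resonant) profiles
        kernel = np.ones(smooth_bins)
        zs = np.convolve(z, kernel, mode="same") / np.convolve(
            np.ones_like(z), kernel, mode="same"
        )
    k = int(np.argmax(zs))
    f_r = float(fb[k])
    z_max = float(zs[k])
    kq = int(np.argmin(np.abs(fb - f_qr)))
    q_r = z_max / float(zs[kq])
    return fb, z, f_r, q_r, z_max


def _halfwidth(v, dt, pk_idx, v_rmp) -> float:
    """Full width (ms) at half-maximum of the AP at ``pk_idx``, re V_RMP."""
    half = v_rmp + (v[pk_idx] - v_rmp) / 2.0
    i = pk_idx
    while i > 0 and v[i] > half:
        i -= 1
    if v[i] == v[i + 1]:
        t_up = i * dt
    else:
        t_up = (i + (half - v[i]) / (v[i + 1] - v[i])) * dt
    j = pk_idx
    while j < len(v) - 1 and v[j] > half:
        j += 1
    if v[j] == v[j - 1]:
        t_dn = j * dt
    else:
        t_dn = (j - (half - v[j]) / (v[j - 1] - v[j])) * dt
    return (t_dn - t_up) * 1e3


def ap_measurements(trace, v_rmp: float, onset_s: float, dur_s: float = 1.0,
                    firing_class: str | None = None) -> dict:
    """AP-train measurements from a 250 pA x 1 s somatic response.

    Returns f_250 (spike count in the injection window), T_1AP and T_1ISI
    (ms), V_AHP (minimum voltage in the first 50 ms minus V_RMP), V_th
    (voltage at the first dV/dt >= 20 V/s crossing of the first spike
    upstroke), T_APHW (half-width of the first spike after 500 ms; only
    for the regular-spiking class, NaN otherwise or when no late spike
    exists), and somatic dV/dt extremes (V/s). NaN marks undefined values.
    """
    v, dt = _trace_arrays(trace)
    t_sp, _ = detect_spikes((v, dt))
    in_win = (t_sp >= onset_s) & (t_sp < onset_s + dur_s)
    t_sp = t_sp[in_win]
    out = {}
    out["f_250"] = float(len(t_sp))
    out["t_1ap"] = (t_sp[0] - onset_s) * 1e3 if len(t_sp) >= 1 else np.nan
    out["t_1isi"] = (t_sp[1] - t_sp[0]) * 1e3 if len(t_sp) >= 2 else np.nan
    i_on = int(round(onset_s / dt))
    i_50 = i_on + int(round(0.05 / dt))
    out["v_ahp"] = float(np.min(v[i_on:i_50]) - v_rmp) if i_50 <= len(v) else np.nan

    dvdt = np.diff(v) / (dt * 1e3)  # mV/ms == V/s
    i_end = i_on + int(round(dur_s / dt))
    seg = dvdt[i_on:i_end]
    out["dvdt_max"] = float(np.max(seg)) if len(seg) else np.nan
    out["dvdt_min"] = float(np.min(seg)) if len(seg) else np.nan

    out["v_th"] = np.nan
    if len(t_sp) >= 1:
        pk = int(round(t_sp[0] / dt))
        j0 = max(i_on, pk - int(round(0.003 / dt)))
        # first sample of the upstroke at which dV/dt reached 20 V/s
        cross = np.flatnonzero(dvdt[j0:pk] >= 20.0)
        if len(cross):
            out["v_th"] = float(v[j0 + cross[0]])

    out["t_aphw"] = np.nan
    if firing_class in (None, "RS"):
        late = t_sp[t_sp >= onset_s + 0.5]
        if len(late):
            pk = int(round(late[0] / dt))
            out["t_aphw"] = _halfwidth(v, dt, pk, v_rmp)
    return out


def bap_amplitudes(traces: dict, onset_s: float, baseline_s: float = 0.01,
                   search_ms: float = 15.0) -> dict:
    """First-AP amplitude (peak minus pre-stimulus baseline) per site.

    ``traces`` maps site tags (must include 'soma') to traces from the
    1 nA x 50 ms somatic injection. The somatic first spike anchors a
    short search window in the dendritic traces, where the back-propagated
    peak is taken. Raises if the soma shows no spike.
    """
    v0, dt = _trace_arrays(traces["soma"])
    t_sp, _ = detect_spikes((v0, dt))
    t_sp = t_sp[t_sp >= onset_s]
    if len(t_sp) == 0:
        raise ValueError("no somatic action potential in the bAP protocol")
    t1 = t_sp[0]
    out = {}
    for tag, tr in traces.items():
        if tag.startswith("_"):
            continue
        v, dt_k = _trace_arrays(tr)
        ib0 = max(0, int(round((onset_s - baseline_s) / dt_k)))
        ib1 = int(round(onset_s / dt_k))
        base = float(np.mean(v[ib0:ib1])) if ib1 > ib0 else float(v[ib1])
        j0 = int(round((t1 - 0.002) / dt_k))
        j1 = int(round((t1 + search_ms * 1e-3) / dt_k))
        out[tag] = float(np.max(v[j0:j1]) - base)
    return out
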