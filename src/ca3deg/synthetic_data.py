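"""Synthetic fixtures with machine-readable ground truth.

Three generator families support testing the trace-analysis and
population-analytics layers without running any cable simulation:

* :func:`gen_trace` — voltage traces built from parameterized spike
  templates (alpha-function-like rise/fall with analytic threshold and
  half-width), optional burst patterns, depolarizing ramp plateaus and
  seeded Gaussian noise; the recipe's ground truth (true spike times,
  amplitudes, ΔV_AP, ramp height) is returned alongside.
* :func:`gen_population_table` — multivariate-normal parameter ×
  measurement surrogate tables realizing a requested correlation
  structure.
* :func:`gen_passive_fixture` — closed-form RC step/chirp responses for
  oracle tests of the resistance/impedance measurements.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTemplate",
    "TraceRecipe",
    "GroundTruth",
    "gen_trace",
    "gen_population_table",
    "gen_passive_fixture",
]


@dataclass(frozen=True)
class SpikeTemplate:
    """Triangular-flank spike with exponential AHP.

    ``height`` mV above baseline, ``rise_ms``/``fall_ms`` the linear flank
    durations, ``ahp_depth`` mV below baseline decaying with ``ahp_tau_ms``.
    The half-width relative to baseline is (rise + fall) / 2 by the
    triangle geometry.
    """

    height: float = 100.0
    rise_ms: float = 0.5
    fall_ms: float = 1.5
    ahp_depth: float = 5.0
    ahp_tau_ms: float = 20.0

    @property
    def halfwidth_ms(self) -> float:
        return (self.rise_ms + self.fall_ms) / 2.0

    @property
    def width_ms(self) -> float:
        return self.rise_ms + self.fall_ms


@dataclass
class TraceRecipe:
    """Declarative voltage-trace construction.

    ``spike_times_ms`` places spikes explicitly; alternatively a burst
    pattern (``n_bursts`` bursts of ``spikes_per_burst`` spikes with
    ``intra_isi_ms`` within and ``inter_gap_ms`` between bursts, starting
    at ``burst_start_ms``). ``amplitudes`` optionally scales each spike's
    height (mV above baseline). A ramp plateau of ``ramp_mV`` spans
    ``ramp_window_ms``. Noise is zero-mean Gaussian, seeded.
    """

    baseline: float = -65.0
    duration_ms: float = 1000.0
    dt_ms: float = 0.025
    template: SpikeTemplate = field(default_factory=SpikeTemplate)
    spike_times_ms: list | None = None
    amplitudes: list | None = None
    n_bursts: int = 0
    spikes_per_burst: int = 3
    intra_isi_ms: float = 8.0
    inter_gap_ms: float = 150.0
    burst_start_ms: float = 50.0
    ramp_mV: float = 0.0
    ramp_window_ms: tuple | None = None
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """What the recipe actually embedded in the trace."""

    spike_times_s: np.ndarray
    amplitudes: np.ndarray  # peak above baseline, mV
    dv_ap: float  # first minus second amplitude, NaN if < 2 spikes
    ramp_mV: float
    halfwidth_ms: float


def _resolve_spike_times(recipe: TraceRecipe) -> np.ndarray:
    if recipe.spike_times_ms is not None:
        t = np.asarray(recipe.spike_times_ms, dtype=float)
    elif recipe.n_bursts > 0:
        t = []
        start = recipe.burst_start_ms
        for _ in range(recipe.n_bursts):
            for k in range(recipe.spikes_per_burst):
                t.append(start + k * recipe.intra_isi_ms)
            start += (recipe.spikes_per_burst - 1) * recipe.intra_isi_ms \
                + recipe.inter_gap_ms
        t = np.asarray(t)
    else:
        t = np.array([])
    if np.any(t < 0) or np.any(t > recipe.duration_ms):
        raise ValueError("spike times outside trace duration")
    if len(t) > 1 and np.min(np.diff(np.sort(t))) < recipe.template.width_ms:
        raise ValueError("overlapping spike templates in recipe")
    return np.sort(t)


def gen_trace(recipe: TraceRecipe):
    """Build the voltage array for a recipe; returns ``(trace, truth)``.

    ``trace`` is ``(samples mV, dt s)``; ``truth`` a :class:`GroundTruth`
    with the constructed spike times (at template peaks), per-spike
    amplitudes, ΔV_AP and ramp height.
    """
    if recipe.dt_ms <= 0:
        raise ValueError("dt must be positive")
    n = int(round(recipe.duration_ms / recipe.dt_ms))
    t_ms = np.arange(n) * recipe.dt_ms
    v = np.full(n, recipe.baseline)

    # ramp plateau: raised-cosine edges for a smooth spike-free pedestal
    true_ramp = 0.0
    if recipe.ramp_mV and recipe.ramp_window_ms is not None:
        a, b = recipe.ramp_window_ms
        edge = min(20.0, (b - a) / 4)
        win = (t_ms >= a) & (t_ms <= b)
        shape = np.ones(n)
        rise = (t_ms >= a) & (t_ms < a + edge)
        fall = (t_ms > b - edge) & (t_ms <= b)
        shape[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - a) / edge))
        shape[fall] = 0.5 * (1 - np.cos(np.pi * (b - t_ms[fall]) / edge))
        v[win] += recipe.ramp_mV * shape[win]
        true_ramp = float(recipe.ramp_mV)

    spike_ms = _resolve_spike_times(recipe)
    tpl = recipe.template
    amps = (np.asarray(recipe.amplitudes, dtype=float)
            if recipe.amplitudes is not None
            else np.full(len(spike_ms), tpl.height))
    if len(amps) != len(spike_ms):
        raise ValueError("amplitudes must match the number of spikes")

    truth_amps = []
    for tk, amp in zip(spike_ms, amps):
        i_pk = int(round(tk / recipe.dt_ms))
        base_here = v[i_pk] if i_pk < n else recipe.baseline
        peak_v = recipe.baseline + amp
        height = peak_v - base_here  # template rides on the ramp pedestal
        i_r = int(round(tpl.rise_ms / recipe.dt_ms))
        i_f = int(round(tpl.fall_ms / recipe.dt_ms))
        for j in range(max(0, i_pk - i_r), min(n, i_pk + 1)):
            v[j] += height * (1 - (i_pk - j) / i_r) if i_r else height
        for j in range(i_pk + 1, min(n, i_pk + i_f + 1)):
            v[j] += height * (1 - (j - i_pk) / i_f)
        # AHP tail after the fall flank
        j0 = i_pk + i_f + 1
        if tpl.ahp_depth > 0 and j0 < n:
            tail = t_ms[j0:] - t_ms[j0]
            v[j0:] -= tpl.ahp_depth * np.exp(-tail / tpl.ahp_tau_ms)
        truth_amps.append(peak_v - recipe.baseline)

    if recipe.noise_sd > 0:
        rng = np.random.default_rng(recipe.seed)
        v = v + rng.normal(0.0, recipe.noise_sd, n)

    truth_amps = np.asarray(truth_amps)
    dv = float(truth_amps[0] - truth_amps[1]) if len(truth_amps) >= 2 else np.nan
    truth = GroundTruth(
        spike_times_s=spike_ms * 1e-3,
        amplitudes=truth_amps,
        dv_ap=dv,
        ramp_mV=true_ramp,
        halfwidth_ms=tpl.halfwidth_ms,
    )
    return (v, recipe.dt_ms * 1e-3), truth


def gen_population_table(n_rows: int, n_cols: int, corr=None, seed: int = 0,
                         col_prefix: str = "m") -> pd.DataFrame:
    """Multivariate-normal surrogate table with a requested correlation.

    ``corr`` is a positive semi-definite correlation matrix (identity by
    default) or a list of ``(i, j, r)`` triples applied to identity.
    Deterministic per seed.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("need at least a 2x2 table")
    if corr is None:
        C = np.eye(n_cols)
    elif isinstance(corr, (list, tuple)):
        C = np.eye(n_cols)
        for i, j, r in corr:
            C[i, j] = C[j, i] = r
    else:
        C = np.asarray(corr, dtype=float)
        if C.shape != (n_cols, n_cols):
            raise ValueError("correlation matrix shape mismatch")
    w, _ = np.linalg.eigh(C)
    if np.min(w) < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n_cols))
    X = rng.standard_normal((n_rows, n_cols)) @ L.T
    return pd.DataFrame(X, columns=[f"{col_prefix}{k}" for k in range(n_cols)])


@dataclass
class PassiveFixture:
    """Closed-form RC cell: responses to step and chirp currents."""

    r_MOhm: float
    tau_ms: float
    v_rest: float = -65.0

    def step_response(self, i_nA: float, t_s, onset_s: float = 0.0):
        """V(t) for a current step of ``i_nA`` starting at ``onset_s``."""
        t = np.asarray(t_s, dtype=float)
        dt = np.maximum(t - onset_s, 0.0)
        return self.v_rest + i_nA * self.r_MOhm * (
            1.0 - np.exp(-dt / (self.tau_ms * 1e-3))
        ) * (t >= onset_s)

    def impedance(self, f_hz):
        """|Z(f)| in MΩ: R / sqrt(1 + (2 pi f tau)^2)."""
        f = np.asarray(f_hz, dtype=float)
        return self.r_MOhm / np.sqrt(1.0 + (2 * np.pi * f * self.tau_ms * 1e-3) ** 2)

    def chirp_response(self, chirp_pA: np.ndarray, dt_s: float):
        """Convolution of the chirp with the RC impulse response (exact
        discrete first-order filter), in mV relative to rest."""
        from scipy.signal import lfilter

        tau = self.tau_ms * 1e-3
        a = np.exp(-dt_s / tau)
        # pA * MOhm = uV, hence the 1e-3 to mV
        drive = chirp_pA * self.r_MOhm * 1e-3 * (1.0 - a)
        v = lfilter([1.0], [1.0, -a], drive)
        return self.v_rest + v


def gen_passive_fixture(r_MOhm: float = 100.0, tau_ms: float = 20.0,
                        v_rest: float = -65.0) -> PassiveFixture:
    """Closed-form passive RC fixture for measurement oracles."""
    if r_MOhm <= 0 or tau_ms <= 0:
        raise ValueError("R and tau must be positive")
    return PassiveFixture(r_MOhm, tau_ms, v_rest)
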