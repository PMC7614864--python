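"""Firing-phenotype analytics: IB/RS classification and population structure.

CA3 pyramidal neurons split into intrinsically bursting (IB) and regular
spiking (RS) phenotypes. A model is classified from its somatic response
to a 240 pA, 5.5 s current step: IB requires three or more spikes within a
25 ms window AND a decrement of the within-burst AP amplitude (first minus
second spike amplitude above a configurable threshold, default 5 mV);
everything else is RS.

Population-structure helpers cover the correlation analyses
(pairwise Pearson matrices over measurement or parameter tables),
dimensionality reduction (PCA and t-SNE) and unpaired rank-based group
comparisons between phenotype classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ca3deg.measurements import detect_spikes

__all__ = [
    "FiringProfile",
    "classify_ib_rs",
    "temporal_profiles",
    "correlation_matrix",
    "embed",
    "compare_groups",
    "isi_histogram",
]

#: minimum first-to-second AP amplitude drop (mV) for the bursting clause
AMP_REDUCTION_THRESHOLD = 5.0
#: burst window (ms): three or more APs within this span
BURST_WINDOW_MS = 25.0


@dataclass
class FiringProfile:
    """Spike times (s), ISIs (s), baseline-relative amplitudes (mV), label."""

    spike_times: np.ndarray
    isis: np.ndarray
    amplitudes: np.ndarray
    label: str  # 'IB' | 'RS'
    low_count: bool = False
    burst_start_index: int | None = None


def classify_ib_rs(trace, v_rmp: float, onset_s: float = 0.0,
                   dur_s: float = 5.5,
                   amp_reduction_mV: float = AMP_REDUCTION_THRESHOLD,
                   burst_window_ms: float = BURST_WINDOW_MS) -> FiringProfile:
    """Classify the 240 pA x 5.5 s somatic response as IB or RS.

    IB iff some run of three consecutive spikes spans at most
    ``burst_window_ms`` AND, within that run, the first amplitude exceeds
    the second by more than ``amp_reduction_mV``. Amplitudes are
    peak minus V_RMP, so the rule is invariant to a trace-wide offset.
    Fewer than three spikes gives RS with ``low_count`` set.
    """
    t_sp, peaks = detect_spikes(trace)
    keep = (t_sp >= onset_s) & (t_sp < onset_s + dur_s)
    t_sp, peaks = t_sp[keep], peaks[keep]
    amps = peaks - v_rmp
    isis = np.diff(t_sp)
    if len(t_sp) < 3:
        return FiringProfile(t_sp, isis, amps, "RS", low_count=True)
    win_s = burst_window_ms * 1e-3
    for i in range(len(t_sp) - 2):
        if t_sp[i + 2] - t_sp[i] <= win_s and amps[i] - amps[i + 1] > amp_reduction_mV:
            return FiringProfile(t_sp, isis, amps, "IB", burst_start_index=i)
    return FiringProfile(t_sp, isis, amps, "RS")


def temporal_profiles(profile: FiringProfile):
    """(ISI vs spike index, amplitude vs spike index) for plotting/statistics.

    ISI index i is the interval following spike i (length = spike count - 1).
    """
    if len(profile.spike_times) < 2:
        raise ValueError("need at least two spikes for temporal profiles")
    idx = np.arange(len(profile.spike_times))
    return (idx[:-1], profile.isis), (idx, profile.amplitudes)


def isi_histogram(profile: FiringProfile, bin_ms: float = 10.0,
                  max_ms: float = 500.0):
    """ISI histogram (counts, bin edges in ms); bimodal for IB neurons."""
    edges = np.arange(0.0, max_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(profile.isis * 1e3, bins=edges)
    return counts, edges


def correlation_matrix(table, min_rows: int = 3):
    """Pairwise Pearson matrix and the unique off-diagonal coefficients.

    ``table`` is a DataFrame or 2D array (rows = models, columns =
    measurements/parameters). Returns ``(matrix, pairs)`` where ``pairs``
    is a DataFrame of the C(k, 2) unique column pairs and their
    coefficients; zero-variance columns yield NaN coefficients which are
    excluded from ``pairs`` (the matrix keeps them as NaN).
    """
    df = pd.DataFrame(table)
    if df.shape[1] < 2:
        raise ValueError("need at least two columns")
    if df.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} rows")
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = df.corr(method="pearson", min_periods=min_rows)
    # pandas leaves unit diagonal even for zero-variance columns; mark NaN
    sd = df.std().to_numpy()
    for j in np.flatnonzero(sd == 0):
        mat.iloc[j, :] = np.nan
        mat.iloc[:, j] = np.nan
    recs = []
    cols = list(df.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = mat.iloc[i, j]
            if np.isfinite(r):
                recs.append({"a": cols[i], "b": cols[j], "r": float(r)})
    pairs = pd.DataFrame(recs, columns=["a", "b", "r"])
    return mat, pairs


def embed(table, method: str = "pca", dims: int = 3, seed: int = 0):
    """Dimensionality reduction of a models x features table.

    ``method='pca'`` returns ``(coords, explained_variance_ratio)`` with a
    deterministic sign convention (largest-magnitude loading of each
    component positive); ``method='tsne'`` returns ``(coords, None)``,
    reproducible for a given seed. Features are z-scored first.
    """
    df = pd.DataFrame(table)
    X = df.to_numpy(dtype=float)
    n, k = X.shape
    if dims >= k:
        raise ValueError("dims must be smaller than the number of columns")
    if n <= dims:
        raise ValueError("need more rows than dims")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    if method == "pca":
        from sklearn.decomposition import PCA

        pca = PCA(n_components=dims, svd_solver="full")
        coords = pca.fit_transform(Xz)
        comps = pca.components_
        for c in range(dims):
            j = np.argmax(np.abs(comps[c]))
            if comps[c, j] < 0:
                comps[c] *= -1.0
                coords[:, c] *= -1.0
        return coords, pca.explained_variance_ratio_
    if method == "tsne":
        from sklearn.manifold import TSNE

        ts = TSNE(n_components=dims, random_state=seed,
                  perplexity=min(30.0, max(5.0, (n - 1) / 4)), init="pca")
        return ts.fit_transform(Xz), None
    raise ValueError(f"unknown embedding method {method!r}")


def compare_groups(values_a, values_b, paired: bool = False):
    """Rank-based two-group comparison; returns (statistic, two-sided p).

    Unpaired groups (the IB vs RS design) use the Wilcoxon rank-sum
    (Mann-Whitney) test; ``paired=True`` or ``values_b=None`` runs the
    one-sample/paired Wilcoxon signed-rank test (used for knockout
    effects against a no-change null).
    """
    a = np.asarray(values_a, dtype=float)
    if values_b is None:
        if len(a) < 3:
            raise ValueError("need at least 3 values")
        res = stats.wilcoxon(a)
        return float(res.statistic), float(res.pvalue)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if paired:
        res = stats.wilcoxon(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
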