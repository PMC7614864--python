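"""IB/RS classification, correlation analytics, embeddings, group tests."""

import numpy as np
import pandas as pd
import pytest

from ca3deg.phenotype import (
    classify_ib_rs,
    compare_groups,
    correlation_matrix,
    embed,
    isi_histogram,
    temporal_profiles,
)
from ca3deg.synthetic_data import TraceRecipe, gen_trace


def _trace_from(times_ms, amps=None, dur=6000.0):
    recipe = TraceRecipe(spike_times_ms=list(times_ms), amplitudes=amps,
                         duration_ms=dur, dt_ms=0.05)
    (v, dt), _ = gen_trace(recipe)
    return (v, dt)


class TestClassify:
    def test_decrementing_triplet_is_ib(self):
        tr = _trace_from([100.0, 110.0, 120.0], amps=[100.0, 88.0, 80.0])
        prof = classify_ib_rs(tr, -65.0)
        assert prof.label == "IB"
        assert prof.burst_start_index == 0

    def test_tonic_constant_amplitude_is_rs(self):
        tr = _trace_from(np.arange(100.0, 5500.0, 100.0))
        prof = classify_ib_rs(tr, -65.0)
        assert prof.label == "RS"
        assert not prof.low_count

    def test_triplet_without_decrement_is_rs(self):
        tr = _trace_from([100.0, 110.0, 120.0], amps=[100.0, 100.0, 100.0])
        assert classify_ib_rs(tr, -65.0).label == "RS"

    def test_slow_triplet_is_rs(self):
        # three spikes but spanning more than 25 ms
        tr = _trace_from([100.0, 120.0, 140.0], amps=[100.0, 88.0, 80.0])
        assert classify_ib_rs(tr, -65.0).label == "RS"

    def test_too_few_spikes_flagged(self):
        tr = _trace_from([100.0, 300.0])
        prof = classify_ib_rs(tr, -65.0)
        assert prof.label == "RS" and prof.low_count

    def test_offset_invariance(self):
        times = [100.0, 110.0, 120.0]
        amps = [100.0, 88.0, 80.0]
        t1 = _trace_from(times, amps)
        v2 = t1[0] + 5.0
        p1 = classify_ib_rs(t1, -65.0)
        p2 = classify_ib_rs((v2, t1[1]), -60.0)
        assert p1.label == p2.label == "IB"


class TestTemporalProfiles:
    def test_flat_isi_profile(self):
        tr = _trace_from(np.arange(100.0, 2000.0, 100.0))
        prof = classify_ib_rs(tr, -65.0)
        (idx, isis), (aidx, amps) = temporal_profiles(prof)
        assert len(isis) == len(prof.spike_times) - 1
        assert np.allclose(isis, 0.1, atol=1e-3)

    def test_burst_pattern_alternates(self):
        recipe = TraceRecipe(n_bursts=3, spikes_per_burst=3, intra_isi_ms=8.0,
                             inter_gap_ms=200.0, duration_ms=2000.0,
                             dt_ms=0.05)
        (v, dt), _ = gen_trace(recipe)
        prof = classify_ib_rs((v, dt), -65.0,
                              amp_reduction_mV=-1.0)  # spikes equal-height
        (_, isis), _ = temporal_profiles(prof)
        short = isis < 0.05
        assert short.tolist() == [True, True, False, True, True, False,
                                  True, True]
        counts, edges = isi_histogram(prof)
        assert counts.sum() == len(isis)

    def test_single_spike_rejected(self):
        tr = _trace_from([500.0])
        prof = classify_ib_rs(tr, -65.0)
        with pytest.raises(ValueError):
            temporal_profiles(prof)


class TestCorrelation:
    @pytest.mark.parametrize("k, n_pairs", [(21, 210), (14, 91), (5, 10)])
    def test_unique_pair_counts(self, k, n_pairs):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, k)))
        mat, pairs = correlation_matrix(df)
        assert len(pairs) == n_pairs
        assert mat.shape == (k, k)
        assert np.allclose(np.diag(mat), 1.0)

    def test_perfect_linear_pair(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": np.sin(x)})
        mat, pairs = correlation_matrix(df)
        r = pairs[(pairs.a == "x") & (pairs.b == "y")].r.iloc[0]
        assert r == pytest.approx(1.0)
        assert np.allclose(mat.values, mat.values.T, equal_nan=True)

    def test_zero_variance_column_excluded(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10),
                           "c": np.arange(10.0) ** 2})
        mat, pairs = correlation_matrix(df)
        assert len(pairs) == 1  # only (a, c) defined
        assert np.isnan(mat.loc["a", "b"])

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


class TestEmbed:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=50)
        X = np.outer(u, [1.0, 2.0, -1.0, 0.5])
        coords, evr = embed(X, "pca", dims=2)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        c1, _ = embed(X, "pca", dims=3)
        perm = rng.permutation(40)
        c2, _ = embed(X[perm], "pca", dims=3)
        assert np.allclose(c2, c1[perm], atol=1e-8)

    def test_reconstruction_error_equals_tail_eigenvalues(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 6))
        sd = X.std(axis=0)
        Xz = (X - X.mean(axis=0)) / sd
        dims = 3
        coords, evr = embed(X, "pca", dims=dims)
        # eigendecomposition oracle on the covariance
        w = np.linalg.eigvalsh(np.cov(Xz.T))[::-1]
        captured = np.sum(coords.var(axis=0, ddof=1))
        assert captured == pytest.approx(np.sum(w[:dims]), rel=1e-6)
        assert np.sum(evr) <= 1.0 + 1e-12

    def test_tsne_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 5))
        c1, _ = embed(X, "tsne", dims=2, seed=9)
        c2, _ = embed(X, "tsne", dims=2, seed=9)
        assert np.allclose(c1, c2)

    def test_dims_too_large_rejected(self):
        with pytest.raises(ValueError):
            embed(np.random.default_rng(0).normal(size=(10, 3)), "pca", dims=3)


class TestCompareGroups:
    def test_identical_groups_nonsignificant(self):
        a = np.arange(30.0)
        stat, p = compare_groups(a, a.copy())
        assert p > 0.9

    def test_widely_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(10.0, 1.0, 30)
        _, p = compare_groups(a, b)
        assert p < 0.001

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(0.5, 1.0, 20)
        s1, p1 = compare_groups(a, b)
        s2, p2 = compare_groups(rng.permutation(a), rng.permutation(b))
        assert (s1, p1) == (s2, p2)

    def test_one_sample_signed_rank_against_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(3.0, 1.0, 20)
        _, p = compare_groups(x, None)
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0, 3.0])
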