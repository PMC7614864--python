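"""Measurement operations against constructed traces and closed-form oracles."""

import numpy as np
import pytest

from ca3deg.measurements import (
    MeasurementBounds,
    ap_measurements,
    bap_amplitudes,
    detect_spikes,
    impedance_profile,
    measure_rin,
    measure_rmp_sd,
    measure_sag,
)
from ca3deg.synthetic_data import (
    SpikeTemplate,
    TraceRecipe,
    gen_passive_fixture,
    gen_trace,
)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        v = np.full(10000, -65.0)
        t, p = detect_spikes((v, 1e-4))
        assert len(t) == 0

    def test_constructed_train_recovered(self):
        recipe = TraceRecipe(spike_times_ms=list(np.arange(7) * 100.0 + 50.0))
        (v, dt), truth = gen_trace(recipe)
        t, p = detect_spikes((v, dt))
        assert len(t) == 7
        assert np.allclose(t, truth.spike_times_s, atol=dt)

    def test_agreement_with_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(2, 9)
            times = np.sort(rng.uniform(20.0, 900.0, n))
            while np.any(np.diff(times) < 5.0):
                times = np.sort(rng.uniform(20.0, 900.0, n))
            recipe = TraceRecipe(spike_times_ms=list(times), dt_ms=0.1,
                                 noise_sd=0.3, seed=int(rng.integers(1e6)))
            (v, dt), _ = gen_trace(recipe)
            t, p = detect_spikes((v, dt))
            # oracle: local maxima above 0 mV separated by >= 1 ms
            above = v >= 0.0
            idx = [i for i in range(1, len(v) - 1)
                   if above[i] and v[i] >= v[i - 1] and v[i] > v[i + 1]]
            keep = []
            for i in idx:
                if not keep or (i - keep[-1]) * dt >= 1e-3:
                    keep.append(i)
            assert len(t) == len(keep) == n


class TestRmpSd:
    def test_constant_trace(self):
        v = np.full(int(6.0 / 1e-4), -65.0)
        rmp, sd = measure_rmp_sd((v, 1e-4))
        assert rmp == -65.0 and sd == 0.0

    def test_sinusoid_sd_closed_form(self):
        dt = 1e-4
        t = np.arange(int(6.0 / dt)) * dt
        v = -65.0 + 0.005 * np.sin(2 * np.pi * 10.0 * t)
        rmp, sd = measure_rmp_sd((v, dt))
        assert sd == pytest.approx(0.005 / np.sqrt(2) * 1e3, rel=1e-3)  # uV

    def test_window_matches_direct_slice(self):
        rng = np.random.default_rng(0)
        dt = 1e-3
        v = rng.normal(-65.0, 1.0, int(6.0 / dt))
        rmp, sd = measure_rmp_sd((v, dt))
        seg = v[int(5.0 / dt):int(6.0 / dt)]
        assert rmp == pytest.approx(np.mean(seg))
        assert sd == pytest.approx(np.std(seg) * 1e3)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            measure_rmp_sd((np.zeros(100), 1e-3))


class TestRin:
    def test_constructed_linearity(self):
        i = np.arange(-50.0, 51.0, 10.0)
        v = -65.0 + 0.1 * i
        assert measure_rin(i, v) == pytest.approx(100.0)

    def test_offset_invariance(self):
        i = np.arange(-50.0, 51.0, 10.0)
        v = -65.0 + 0.08 * i
        assert measure_rin(i, v + 7.0) == pytest.approx(measure_rin(i, v))

    def test_passive_fixture_within_tenth_percent(self):
        fx = gen_passive_fixture(r_MOhm=120.0, tau_ms=20.0)
        i_pA = np.arange(-50.0, 51.0, 10.0)
        t = np.linspace(0, 0.3, 3001)
        v_ss = [fx.step_response(i * 1e-3, t)[-1] for i in i_pA]
        assert measure_rin(i_pA, v_ss) == pytest.approx(120.0, rel=1e-3)

    def test_singular_fit_rejected(self):
        with pytest.raises(ValueError):
            measure_rin([10.0, 10.0], [-64.0, -63.0])


class TestSag:
    def test_pure_rc_has_no_sag(self):
        fx = gen_passive_fixture(100.0, 20.0)
        dt = 1e-4
        t = np.arange(int(1.0 / dt)) * dt
        v = fx.step_response(-0.25, t, onset_s=0.1)
        assert measure_sag((v, dt), onset_s=0.1, dur_s=0.8) == \
            pytest.approx(1.0, abs=0.01)

    def test_constructed_ratio(self):
        dt = 1e-4
        n = int(1.0 / dt)
        v = np.full(n, -65.0)
        i0, i1 = int(0.1 / dt), int(0.9 / dt)
        t_rel = np.arange(i1 - i0) * dt
        # fast drop to -10 mV deflection, relaxing to -9.4 mV steady
        v[i0:i1] = -65.0 - 9.4 - 0.6 * np.exp(-t_rel / 0.05)
        v[i0] = -75.0  # peak deflection exactly -10
        sag = measure_sag((v, dt), onset_s=0.1, dur_s=0.8)
        assert sag == pytest.approx(0.94, abs=0.005)

    def test_missing_deflection_rejected(self):
        v = np.full(10000, -65.0)
        with pytest.raises(ValueError):
            measure_sag((v, 1e-4), onset_s=0.1, dur_s=0.8)


class TestImpedance:
    def test_rc_profile_matches_closed_form(self):
        from ca3deg.simulator import make_chirp

        fx = gen_passive_fixture(100.0, 20.0)
        dt = 1e-3
        chirp = make_chirp(100.0, 0.0, 15.0, 15.0, dt)
        v = fx.chirp_response(chirp, dt)
        freqs, z, f_r, q_r, z_max = impedance_profile(
            (v, dt), (chirp, dt), baseline=fx.v_rest
        )
        pred = fx.impedance(freqs)
        assert np.max(np.abs(z - pred) / pred) < 0.03
        # lowpass: peak within a couple of bins of the lowest evaluated
        assert f_r <= freqs[0] + 2.0 / 15.0
        assert q_r == pytest.approx(1.0, abs=0.02)

    def test_resonant_kernel_peak_recovered(self):
        # band-pass kernel with an analytic peak, driven by the chirp:
        # |H| = 1/|1 + iQ(f/f0 - f0/f)| peaks exactly at f0
        from ca3deg.simulator import make_chirp

        dt = 1e-3
        chirp = make_chirp(100.0, 0.0, 15.0, 15.0, dt)
        n = len(chirp)
        freqs = np.fft.rfftfreq(n, dt)
        f0 = 4.0
        with np.errstate(divide="ignore"):
            h = 1.0 / (1.0 + 0.5j * (freqs / f0 -
                                     np.where(freqs > 0, f0 / np.maximum(freqs, 1e-12), 0.0)))
        h[0] = abs(h[1])
        v = np.fft.irfft(np.fft.rfft(chirp) * h, n)
        _, z, f_r, _, _ = impedance_profile((v, dt), (chirp, dt), baseline=0.0)
        assert f_r == pytest.approx(f0, abs=0.25)

    def test_linearity_in_voltage(self):
        from ca3deg.simulator import make_chirp

        fx = gen_passive_fixture(80.0, 30.0)
        dt = 1e-3
        chirp = make_chirp(100.0, 0.0, 15.0, 15.0, dt)
        v = fx.chirp_response(chirp, dt) - fx.v_rest
        _, z1, *_ = impedance_profile((v, dt), (chirp, dt), baseline=0.0)
        _, z2, *_ = impedance_profile((2 * v, dt), (chirp, dt), baseline=0.0)
        assert np.allclose(z2, 2 * z1)

    def test_mismatched_sampling_rejected(self):
        with pytest.raises(ValueError):
            impedance_profile((np.zeros(100), 1e-3), (np.zeros(99), 1e-3))


class TestApMeasurements:
    def test_spike_count_in_window(self):
        recipe = TraceRecipe(spike_times_ms=list(np.linspace(150, 950, 6)),
                             duration_ms=1100.0)
        (v, dt), _ = gen_trace(recipe)
        out = ap_measurements((v, dt), -65.0, onset_s=0.1, dur_s=1.0)
        assert out["f_250"] == 6

    def test_threshold_at_20Vps_crossing(self):
        dt = 1e-5
        n = 30000
        v = np.full(n, -65.0)
        i0 = 10000
        up = 12000
        # 30 V/s linear ramp then fast spike upstroke
        v[i0:up] = -65.0 + 30.0 * (np.arange(up - i0) * dt)  # 30 V/s
        pk = up + 200
        v[up:pk] = v[up - 1] + 400.0 * (np.arange(pk - up) * dt) * 1e3
        v[pk:pk + 300] = np.linspace(v[pk - 1], -70.0, 300)
        out = ap_measurements((v, dt), -65.0, onset_s=0.05, dur_s=0.25)
        assert out["v_th"] == pytest.approx(-65.0, abs=1.0)

    def test_triangular_halfwidth_geometry(self):
        tpl = SpikeTemplate(height=100.0, rise_ms=0.5, fall_ms=1.5,
                            ahp_depth=0.0)
        recipe = TraceRecipe(spike_times_ms=[700.0], template=tpl,
                             duration_ms=1200.0)
        (v, dt), truth = gen_trace(recipe)
        out = ap_measurements((v, dt), -65.0, onset_s=0.1, dur_s=1.0,
                              firing_class="RS")
        assert out["t_aphw"] == pytest.approx(truth.halfwidth_ms, rel=0.05)

    def test_single_spike_has_undefined_isi(self):
        recipe = TraceRecipe(spike_times_ms=[300.0])
        (v, dt), _ = gen_trace(recipe)
        out = ap_measurements((v, dt), -65.0, onset_s=0.1, dur_s=1.0)
        assert np.isnan(out["t_1isi"])
        assert out["t_1ap"] == pytest.approx(200.0, abs=1.0)


class TestBapAmplitudes:
    def _trace(self, peak, dt=1e-5, t_spike=0.105):
        n = 20000
        v = np.full(n, -65.0)
        i = int(t_spike / dt)
        v[i - 50:i] = np.linspace(-65.0, peak, 50)
        v[i:i + 150] = np.linspace(peak, -65.0, 150)
        return (v, dt)

    def test_identical_traces_equal_amplitudes(self):
        tr = {"soma": self._trace(35.0), "apical_150": self._trace(35.0),
              "apical_300": self._trace(35.0)}
        amps = bap_amplitudes(tr, onset_s=0.1)
        assert amps["soma"] == amps["apical_150"] == amps["apical_300"]

    def test_constructed_peaks_recovered_exactly(self):
        tr = {"soma": self._trace(35.0), "apical_150": self._trace(15.0),
              "apical_300": self._trace(0.0)}
        amps = bap_amplitudes(tr, onset_s=0.1)
        assert amps["soma"] == pytest.approx(100.0, abs=1e-6)
        assert amps["apical_150"] == pytest.approx(80.0, abs=1e-6)
        assert amps["apical_300"] == pytest.approx(65.0, abs=1e-6)

    def test_attenuation_monotone_on_decaying_fixture(self):
        tr = {"soma": self._trace(40.0), "apical_150": self._trace(20.0),
              "apical_300": self._trace(5.0)}
        amps = bap_amplitudes(tr, onset_s=0.1)
        assert amps["soma"] > amps["apical_150"] > amps["apical_300"]

    def test_no_spike_rejected(self):
        v = np.full(20000, -65.0)
        with pytest.raises(ValueError, match="no somatic"):
            bap_amplitudes({"soma": (v, 1e-5)}, onset_s=0.1)


class TestBounds:
    def test_default_table_wellformed(self):
        b = MeasurementBounds()
        assert b["r_in"] == (60.0, 150.0)
        assert len(b.names()) == 11

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            MeasurementBounds(bounds={"r_in": (10.0, 5.0)})
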