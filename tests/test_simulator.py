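"""Solver oracles: RC and cable closed forms, chirp stimulus, stabilization."""

import numpy as np
import pytest

from ca3deg import simulator as sim
from ca3deg.morphology import Section, SectionTree, discretize
from ca3deg.mpmoss import ParameterVector


def passive_cfg():
    return sim.SolverConfig(v_init=-65.0, e_leak=-65.0)


class TestPassiveOracles:
    def test_rc_step_response_matches_closed_form(self, single_soma,
                                                  passive_params):
        cfg = passive_cfg()
        area = single_soma.total_area()
        r_mohm = 60e3 / area * 1e-6
        tau_ms = 60e3 * 0.75e-6 * 1e3  # R_m C_m = 45 ms
        amp = 0.005  # nA, keeps the deflection well inside the table range
        proto = sim.Protocol(settle_s=0.05,
                             stimuli=[sim.StepStim("soma", amp, 0.0, 300.0)])
        tr = sim.run(single_soma, passive_params, proto, config=cfg)
        v = tr["soma"].samples
        dt = tr["soma"].dt
        i0 = int(round(0.05 / dt))
        t_ms = (np.arange(len(v)) - i0) * dt * 1e3
        pred = -65.0 + amp * r_mohm * (1 - np.exp(-np.maximum(t_ms, 0) / tau_ms))
        steady = amp * r_mohm
        assert np.max(np.abs(v[i0:] - pred[i0:])) < 0.01 * steady

    def test_quiescent_voltage_is_flat(self, single_soma, passive_params):
        proto = sim.Protocol(settle_s=1.5, stimuli=[])
        tr = sim.run(single_soma, passive_params, proto, config=passive_cfg())
        v = tr["soma"].samples
        tail = v[len(v) // 2:]
        assert np.std(tail) * 1e3 < 0.01  # uV-scale criterion evaluable

    def test_cable_attenuation_matches_cosh_profile(self, passive_params):
        # sealed-end finite cable: V(x)/V(0) = cosh((L-x)/lam) / cosh(L/lam)
        L, d = 600.0, 2.0
        t = SectionTree([
            Section(0, -1, "soma", np.array([[0.0, 0.0, 0.0, 2.0]])),
            Section(1, 0, "apical",
                    np.array([[0.0, 1.0, 0.0, d], [0.0, 1.0 + L, 0.0, d]])),
        ])
        m = discretize(t, d_lambda=0.02)  # fine discretization
        cfg = passive_cfg()
        proto = sim.Protocol(
            settle_s=0.3,
            stimuli=[sim.StepStim(0, 0.002, 0.0, 400.0)],
            record_sites=tuple(range(0, m.n_comp, max(1, m.n_comp // 12))),
        )
        tr = sim.run(m, passive_params, proto, config=cfg)
        lam = np.sqrt(60e3 * (d * 1e-4) / (4 * 200.0)) * 1e4  # um
        v0 = None
        for site, trace in tr.items():
            if site.startswith("_"):
                continue
            comp = int(site.split("_")[1])
            x = m.path_um[comp]
            vss = float(np.mean(trace.samples[-400:])) + 65.0
            if comp == 0:
                v0 = vss
        assert v0 is not None
        for site, trace in tr.items():
            if site.startswith("_"):
                continue
            comp = int(site.split("_")[1])
            x = m.path_um[comp]
            vss = float(np.mean(trace.samples[-400:])) + 65.0
            pred = v0 * np.cosh((L - x) / lam) / np.cosh(L / lam)
            assert vss == pytest.approx(pred, rel=0.02)

    def test_halving_dt_keeps_peak_time(self, single_soma, base_params):
        # convergence: somatic AP peak time moves by < 1 coarse step
        def peak_time(dt_us):
            cfg = sim.SolverConfig(dt_us=dt_us)
            proto = sim.Protocol(settle_s=0.5,
                                 stimuli=[sim.StepStim("soma", 0.02, 0.0, 300.0)])
            tr = sim.run(single_soma, base_params, proto, config=cfg)
            v = tr["soma"].samples
            return np.argmax(v) * tr["soma"].dt

        t25 = peak_time(25.0)
        t125 = peak_time(12.5)
        assert abs(t25 - t125) <= 25e-6 + 1e-12


class TestChirp:
    def test_end_frequency_and_amplitude(self):
        dt = 25e-6
        w = sim.make_chirp(100.0, 0.0, 15.0, 15.0, dt)
        assert np.max(w) - np.min(w) == pytest.approx(100.0, rel=1e-3)
        # final zero-crossing interval -> half period of ~15 Hz
        sign = np.sign(w)
        zc = np.flatnonzero(np.diff(sign) != 0)
        half_period = (zc[-1] - zc[-2]) * dt
        assert 1.0 / (2 * half_period) == pytest.approx(15.0, rel=0.05)
        assert sim.chirp_instantaneous_frequency(15.0) == pytest.approx(15.0)

    def test_degenerate_band_rejected(self):
        with pytest.raises(ValueError):
            sim.make_chirp(100.0, 5.0, 5.0, 15.0)

    def test_pure_tone_fft_peak(self):
        dt = 1e-4
        dur = 10.0
        t = np.arange(int(dur / dt)) * dt
        w = 50.0 * np.sin(2 * np.pi * 3.0 * t)
        freqs = np.fft.rfftfreq(len(w), dt)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(w)))]
        assert peak == pytest.approx(3.0, abs=1.0 / dur)

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError, match="20 samples"):
            sim.make_chirp(100.0, 0.0, 15.0, 15.0, dt=5e-3)


class TestStabilize:
    def test_passive_settles_to_rest(self, single_soma, passive_params):
        state, resid, warn = sim.stabilize(single_soma, passive_params, 0.5,
                                           config=passive_cfg())
        assert state.v[0] == pytest.approx(-65.0, abs=1e-6)
        assert resid < 1e-6
        assert not warn

    def test_zero_duration_returns_initial_condition(self, single_soma,
                                                     passive_params):
        state, resid, warn = sim.stabilize(single_soma, passive_params, 0.0,
                                           config=passive_cfg())
        assert np.all(state.v == -65.0)
        assert resid == 0.0

    def test_base_model_settles(self, model, base_params):
        state, resid, warn = sim.stabilize(model, base_params, 2.0)
        assert np.all(np.isfinite(state.v))
        assert resid < 1e-2


class TestDeterminism:
    def test_identical_runs_bit_identical(self, single_soma, base_params):
        proto = sim.Protocol(settle_s=0.2,
                             stimuli=[sim.StepStim("soma", 0.02, 0.0, 100.0)])
        tr1 = sim.run(single_soma, base_params, proto)
        tr2 = sim.run(single_soma, base_params, proto)
        assert np.array_equal(tr1["soma"].samples, tr2["soma"].samples)
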