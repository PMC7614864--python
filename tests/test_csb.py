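"""Complex-spike-burst scoring: ramp measurement, pulse validity, rate."""

import numpy as np
import pytest

from ca3deg.csb import (
    CSB_PROTOCOLS,
    CSBCriteria,
    csb_rate,
    ramp_amplitude,
    run_csb_protocol,
    score_pulse,
)
from ca3deg.synthetic_data import SpikeTemplate, TraceRecipe, gen_trace


def burst_trace(amps, ramp_mV=20.0, times_ms=(60.0, 70.0, 80.0),
                dur_ms=180.0):
    tpl = SpikeTemplate(height=100.0, ahp_depth=0.0)
    recipe = TraceRecipe(
        spike_times_ms=list(times_ms),
        amplitudes=list(amps),
        template=tpl,
        duration_ms=dur_ms,
        dt_ms=0.05,
        ramp_mV=ramp_mV,
        ramp_window_ms=(30.0, dur_ms - 20.0),
    )
    (v, dt), truth = gen_trace(recipe)
    return (v, dt), truth


class TestRampAmplitude:
    def test_constant_trace_zero(self):
        v = np.full(40000, -65.0)
        assert ramp_amplitude((v, 2.5e-5), -65.0) == pytest.approx(0.0,
                                                                   abs=1e-9)

    def test_narrow_spikes_removed(self):
        recipe = TraceRecipe(spike_times_ms=list(np.arange(100.0, 900.0, 90.0)),
                             duration_ms=1000.0, dt_ms=0.05,
                             template=SpikeTemplate(ahp_depth=0.0))
        (v, dt), _ = gen_trace(recipe)
        assert ramp_amplitude((v, dt), -65.0) < 0.5

    def test_plateau_with_spikes_recovered(self):
        (v, dt), truth = burst_trace([100.0, 85.0, 78.0], ramp_mV=20.0,
                                     dur_ms=600.0,
                                     times_ms=(200.0, 210.0, 220.0))
        assert ramp_amplitude((v, dt), -65.0) == pytest.approx(20.0, abs=0.5)


class TestScorePulse:
    def test_valid_burst_all_clauses(self):
        tr, _ = burst_trace([100.0, 85.0, 78.0])
        score = score_pulse(tr, -65.0)
        assert score.ap_clause and score.dvap_clause and score.ramp_clause
        assert score.valid
        assert score.dv_ap == pytest.approx(15.0, abs=1.0)

    def test_small_amplitude_drop_invalid(self):
        tr, _ = burst_trace([100.0, 95.0, 90.0])  # dV_AP = 5
        score = score_pulse(tr, -65.0)
        assert score.ap_clause and not score.dvap_clause
        assert not score.valid

    def test_oversized_ramp_invalid(self):
        tr, _ = burst_trace([100.0, 85.0, 78.0], ramp_mV=35.0)
        score = score_pulse(tr, -65.0)
        assert score.ramp_clause is False
        assert not score.valid

    def test_slow_spikes_fail_ap_clause(self):
        tr, _ = burst_trace([100.0, 85.0, 78.0],
                            times_ms=(40.0, 80.0, 120.0))
        score = score_pulse(tr, -65.0)
        assert not score.ap_clause and not score.valid

    def test_single_spike_dvap_undefined(self):
        tr, _ = burst_trace([100.0], times_ms=(60.0,))
        score = score_pulse(tr, -65.0)
        assert np.isnan(score.dv_ap)
        assert not score.valid

    def test_raising_plateau_flips_only_ramp_clause(self):
        lo, _ = burst_trace([100.0, 85.0, 78.0], ramp_mV=5.0)
        hi, _ = burst_trace([100.0, 85.0, 78.0], ramp_mV=20.0)
        s_lo = score_pulse(lo, -65.0)
        s_hi = score_pulse(hi, -65.0)
        assert not s_lo.ramp_clause and s_hi.ramp_clause
        assert s_lo.ap_clause == s_hi.ap_clause
        assert s_lo.dvap_clause == s_hi.dvap_clause

    def test_pure_function_of_inputs(self):
        tr, _ = burst_trace([100.0, 85.0, 78.0])
        s1 = score_pulse(tr, -65.0)
        s2 = score_pulse(tr, -65.0)
        assert s1 == s2


class TestCsbRate:
    def test_all_later_pulses_valid(self):
        assert csb_rate([True, True, True, True, True]) == 1.0

    def test_none_valid(self):
        assert csb_rate([True, False, False, False, False]) == 0.0

    def test_half_valid_excludes_first_pulse(self):
        assert csb_rate([False, True, False, True, False]) == 0.5

    def test_wrong_pulse_count_rejected(self):
        with pytest.raises(ValueError, match="5"):
            csb_rate([True, True, True])


class TestProtocols:
    def test_protocol_table_geometry(self):
        p900 = CSB_PROTOCOLS["somatic900"]
        assert p900.n_pulses == 5
        assert p900.width_ms == 100.0 and p900.gap_ms == 80.0
        pd_ = CSB_PROTOCOLS["dendritic1000"]
        assert pd_.width_ms == 50.0 and pd_.gap_ms == 50.0
        assert pd_.site_um == 150.0
        syn = CSB_PROTOCOLS["synaptic5Hz"]
        assert syn.period_ms == pytest.approx(200.0)

    def test_somatic_run_has_five_pulse_segments(self, model, base_params):
        from ca3deg import simulator as sim

        spec = CSB_PROTOCOLS["somatic900"]
        cell = sim.compile_cell(model, base_params, sim.SolverConfig())
        state, _, _ = sim.stabilize(model, base_params, 0.5, cell=cell)
        traces = run_csb_protocol(model, base_params, spec,
                                  init_state=state, cell=cell)
        dur_s = len(traces["soma"].samples) * traces["soma"].dt
        assert dur_s == pytest.approx(5 * 0.18, abs=0.01)

    def test_dendritic_site_resolves_near_150um(self, model):
        comp = model.nearest_compartment(150.0, "apical")
        assert abs(model.path_um[comp] - 150.0) <= model.length[comp]

    def test_synaptic_without_synapses_rejected(self, model, base_params):
        with pytest.raises(ValueError, match="synapses"):
            run_csb_protocol(model, base_params,
                             CSB_PROTOCOLS["synaptic5Hz"])
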