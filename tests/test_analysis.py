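"""Spike-train metrics and the behavior classifier on synthetic traces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ucnsim as u
from ucnsim import (
    AnalysisError,
    ClassifierRules,
    SpikeTrain,
    adaptation_index,
    classify_behavior,
    classify_excitability,
    detect_bursts,
    detect_spikes,
    interspike_intervals,
    latency,
    make_stimulus,
)

from conftest import make_pulse_trace


class TestDetectSpikes:
    def test_silent_trace_yields_empty_train(self):
        tr = make_pulse_trace([], t_end=1e-3)
        assert len(detect_spikes(tr, 2.5)) == 0

    def test_onsets_at_rising_edges(self):
        tr = make_pulse_trace([1e-3, 6e-3, 11e-3], width=2e-4)
        sp = detect_spikes(tr, 2.5, t_refractory=1e-3)
        assert len(sp) == 3
        np.testing.assert_allclose(sp.times, [1e-3, 6e-3, 11e-3], atol=2e-5)

    def test_close_crossings_merged(self):
        tr = make_pulse_trace([1e-3, 1.1e-3], width=4e-5, dt=1e-6)
        assert len(detect_spikes(tr, 2.5, t_refractory=1e-3)) == 1

    def test_empty_trace_is_an_error(self):
        tr = make_pulse_trace([], t_end=1e-3)
        empty = u.Trace(t=np.array([]), u=np.array([]), v_mem=np.array([]),
                        v_out=np.array([]), conducting=np.array([]), dt_nominal=1e-6)
        with pytest.raises(AnalysisError):
            detect_spikes(empty, 2.5)
        assert len(detect_spikes(tr, 2.5)) == 0  # silent-but-nonempty is fine

    def test_concatenation_equals_per_piece_detection(self):
        # junction gap far exceeds the refractory window
        t1 = make_pulse_trace([1e-3, 3e-3], width=2e-4, t_end=5e-3)
        t2 = make_pulse_trace([1e-3, 3e-3], width=2e-4, t_end=5e-3)
        joined = u.Trace(
            t=np.concatenate([t1.t, t2.t + 5e-3]),
            u=np.concatenate([t1.u, t2.u]),
            v_mem=np.concatenate([t1.v_mem, t2.v_mem]),
            v_out=np.concatenate([t1.v_out, t2.v_out]),
            conducting=np.concatenate([t1.conducting, t2.conducting]),
            dt_nominal=t1.dt_nominal,
        )
        ref = np.concatenate([detect_spikes(t1, 2.5, 1e-4).times,
                              detect_spikes(t2, 2.5, 1e-4).times + 5e-3])
        np.testing.assert_allclose(detect_spikes(joined, 2.5, 1e-4).times, ref)


class TestIntervalMetrics:
    def test_isis(self):
        assert list(interspike_intervals(SpikeTrain([0.0, 1.0, 3.0]))) == [1.0, 2.0]
        assert list(interspike_intervals(SpikeTrain([0.0, 1.0]))) == [1.0]
        with pytest.raises(AnalysisError):
            interspike_intervals(SpikeTrain([5.0]))

    @pytest.mark.parametrize(
        "isis, expected",
        [([1.0, 1.0, 1.0], 0.0), ([1.0, 2.0, 3.0], 0.5), ([3.0, 2.0, 1.0], -0.5)],
    )
    def test_adaptation_index_values(self, isis, expected):
        assert adaptation_index(isis) == pytest.approx(expected)

    def test_adaptation_index_needs_two_isis(self):
        with pytest.raises(AnalysisError):
            adaptation_index([1.0])

    @settings(deadline=None)
    @given(st.lists(st.floats(1e-4, 10.0), min_size=2, max_size=20))
    def test_adaptation_index_antisymmetric_and_bounded(self, isis):
        ai = adaptation_index(isis)
        assert -1.0 < ai < 1.0
        assert adaptation_index(isis[::-1]) == pytest.approx(-ai, abs=1e-12)


class TestBursts:
    def test_two_clean_bursts(self):
        sp = SpikeTrain(np.array([0.0, 1.0, 2.0, 50.0, 51.0, 52.0]) * 1e-3)
        bursts = detect_bursts(sp, isi_intra=5e-3, isi_inter=20e-3)
        assert [len(b) for b in bursts] == [3, 3]

    def test_regular_train_has_no_bursts(self):
        sp = SpikeTrain(np.arange(10) * 10e-3)
        assert detect_bursts(sp, isi_intra=5e-3, isi_inter=20e-3) == []

    def test_empty_train(self):
        assert detect_bursts(SpikeTrain([]), 1e-3, 2e-3) == []

    def test_insufficient_separation_disqualifies_group(self):
        # the tight pair is only 8 ms from the next spike (< isi_inter)
        sp = SpikeTrain(np.array([0.0, 1.0, 9.0]) * 1e-3)
        assert detect_bursts(sp, isi_intra=5e-3, isi_inter=20e-3) == []

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(AnalysisError):
            detect_bursts(SpikeTrain([]), 2e-3, 1e-3)


class TestExcitabilityRule:
    def test_low_minimum_rate_is_class1(self):
        fi = [(1, 0.0), (2, 0.0), (3, 0.5), (4, 1.2), (5, 2.0)]
        assert classify_excitability(fi, f_eps=1.0, f_jump=20.0) == "class1_excitable"

    def test_rate_jump_is_class2(self):
        fi = [(1, 0.0), (2, 0.0), (3, 40.0), (4, 45.0)]
        assert classify_excitability(fi, f_eps=1.0, f_jump=20.0) == "class2_excitable"

    def test_degenerate_curves_unclassified(self):
        assert classify_excitability([(1, 0.0), (2, 0.0)], 1.0, 20.0) == "unclassified"
        assert classify_excitability([(1, 5.0), (2, 6.0)], 1.0, 20.0) == "unclassified"


class TestLatency:
    def test_values_and_boundary(self):
        assert latency(SpikeTrain([12e-3]), 10e-3) == pytest.approx(2e-3)
        assert latency(SpikeTrain([10e-3]), 10e-3) == 0.0

    def test_no_spike_after_onset_is_an_error(self):
        with pytest.raises(AnalysisError):
            latency(SpikeTrain([5e-3]), 10e-3)


class TestClassifier:
    RULES = ClassifierRules(isi_intra=2e-3, isi_inter=8e-3, tau=1e-3)

    def step(self):
        return make_stimulus("step", t_on=1e-3, amplitude=1e-6)

    def test_silent(self):
        tr = make_pulse_trace([], t_end=20e-3)
        assert classify_behavior(tr, self.step(), self.RULES) == "silent"

    def test_tonic_regular_train(self):
        tr = make_pulse_trace(1e-3 + np.arange(1, 10) * 2e-3, width=2e-4, t_end=20e-3)
        assert classify_behavior(tr, self.step(), self.RULES) == "tonic_spiking"

    def test_single_onset_spike_is_phasic(self):
        tr = make_pulse_trace([2e-3], width=2e-4, t_end=20e-3)
        assert classify_behavior(tr, self.step(), self.RULES) == "phasic_spiking"

    def test_lone_burst_is_phasic_bursting(self):
        tr = make_pulse_trace([2e-3, 3e-3, 4e-3], width=2e-4, t_end=30e-3)
        assert classify_behavior(tr, self.step(), self.RULES) == "phasic_bursting"

    def test_burst_then_regular_tail_is_mixed(self):
        times = [2e-3, 3e-3, 4e-3] + list(15e-3 + np.arange(4) * 12e-3)
        tr = make_pulse_trace(times, width=2e-4, t_end=60e-3)
        assert classify_behavior(tr, self.step(), self.RULES) == "mixed"

    def test_lengthening_isis_are_adaptation(self):
        times = np.cumsum([2e-3, 2e-3, 2.5e-3, 3.2e-3, 4.1e-3, 5.5e-3])
        tr = make_pulse_trace(times, width=2e-4, t_end=25e-3)
        assert classify_behavior(tr, self.step(), self.RULES) == "spike_frequency_adaptation"

    def test_late_first_spike_is_latency(self):
        tr = make_pulse_trace([6e-3, 12e-3], width=2e-4, t_end=20e-3)
        # latency 5 ms > 3 * tau*ln3 = 3.3 ms
        assert classify_behavior(tr, self.step(), self.RULES) == "spike_latency"

    def test_spike_after_negative_pulse_offset_is_rebound(self):
        stim = make_stimulus("negative_pulse", t_on=1e-3, amplitude=-1e-6, width=3e-3)
        tr = make_pulse_trace([5e-3], width=2e-4, t_end=20e-3)
        assert classify_behavior(tr, stim, self.RULES) == "rebound_spike"

    def test_sustained_firing_under_negative_step_is_inhibition_induced(self):
        stim = make_stimulus("negative_step", t_on=1e-3, amplitude=-1e-6)
        tr = make_pulse_trace(1e-3 + np.arange(1, 8) * 2e-3, width=2e-4, t_end=20e-3)
        assert classify_behavior(tr, stim, self.RULES) == "inhibition_induced_spiking"

    def test_total_and_deterministic(self):
        # an awkward pattern still gets exactly one label, stably
        tr = make_pulse_trace([2e-3, 11e-3], width=2e-4, t_end=20e-3)
        labels = {classify_behavior(tr, self.step(), self.RULES) for _ in range(3)}
        assert len(labels) == 1
        assert labels.pop() in u.BEHAVIOR_LABELS
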