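"""Unit and property tests for the hysteretic SCR and axon models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ucnsim import (
    AxonParams,
    ConfigurationError,
    InputError,
    SCRParams,
    SCRState,
    axon_output,
    effective_threshold,
    scr_current,
    scr_next_state,
)

PARAMS = SCRParams(v_th0=2.0, v_th_min=0.5, alpha_gate=1.0, i_hold=1e-5,
                   r_off=1e7, r_on=10.0, v_on=1.0)


class TestSCRCurrent:
    @pytest.mark.parametrize(
        "conducting, v_ak, expected",
        [
            (False, 1.0, 1.0e-7),        # blocking: Ohm's law through r_off
            (True, 1.0, 0.0),            # conducting at the forward drop: zero overdrive
            (True, 2.0, 0.1),            # conducting: (v_ak - v_on) / r_on
            (False, -1.0, -1.0e-7),      # reverse bias blocks in the blocking state
            (True, -1.0, -1.0e-7),       # ... and in the conducting state (diode-like)
        ],
    )
    def test_branch_currents(self, conducting, v_ak, expected):
        state = SCRState(conducting=conducting)
        assert scr_current(state, v_ak, PARAMS) == pytest.approx(expected, abs=1e-15)

    def test_non_finite_voltage_rejected(self):
        with pytest.raises(InputError):
            scr_current(SCRState(), float("nan"), PARAMS)

    def test_continuous_within_each_state(self):
        # small voltage perturbation -> small current change, in both branches
        for conducting in (False, True):
            state = SCRState(conducting=conducting)
            v = np.linspace(0.0, 3.0, 301)
            i = np.array([scr_current(state, float(vv), PARAMS) for vv in v])
            assert np.all(np.abs(np.diff(i)) < 2e-3)


class TestEffectiveThreshold:
    def test_zero_drive_gives_nominal(self):
        assert effective_threshold(0.0, PARAMS) == PARAMS.v_th0

    def test_clamped_at_floor(self):
        assert effective_threshold(10.0, PARAMS) == PARAMS.v_th_min

    def test_negative_drive_rejected(self):
        with pytest.raises(InputError):
            effective_threshold(-0.1, PARAMS)

    @settings(deadline=None)
    @given(g1=st.floats(0, 20), g2=st.floats(0, 20))
    def test_monotone_non_increasing_and_bounded(self, g1, g2):
        lo, hi = sorted((g1, g2))
        th_lo, th_hi = effective_threshold(lo, PARAMS), effective_threshold(hi, PARAMS)
        assert th_hi <= th_lo
        assert PARAMS.v_th_min <= th_hi <= PARAMS.v_th0
        assert PARAMS.v_th_min <= th_lo <= PARAMS.v_th0


class TestTransitions:
    def test_subthreshold_blocking_unchanged(self):
        s = SCRState(conducting=False)
        assert scr_next_state(s, 1.9, 1e-7, 0.0, 1.0, PARAMS) is s

    def test_threshold_switches_on(self):
        s = scr_next_state(SCRState(conducting=False), 2.0, 1e-7, 0.0, 1.0, PARAMS)
        assert s.conducting and s.last_switch_time == 1.0

    def test_holding_current_switches_off(self):
        s = scr_next_state(SCRState(conducting=True), 1.0, 5e-6, 0.0, 2.0, PARAMS)
        assert not s.conducting

    def test_gate_drive_lowers_switching_voltage(self):
        # at v_ak = 1.5 V: blocking without gate drive, fires with 1 V of drive
        stay = scr_next_state(SCRState(conducting=False), 1.5, 0.0, 0.0, 1.0, PARAMS)
        fire = scr_next_state(SCRState(conducting=False), 1.5, 0.0, 1.0, 1.0, PARAMS)
        assert not stay.conducting and fire.conducting


def quasi_static_sweep(params, v_peak=3.0, n=600):
    """Sweep v_ak 0 -> v_peak -> 0; returns (v, i, switch directions)."""
    v_up = np.linspace(0, v_peak, n)
    v_path = np.concatenate([v_up, v_up[::-1]])
    state = SCRState(conducting=False)
    currents, switches = [], []
    for k, v in enumerate(v_path):
        i = scr_current(state, float(v), params)
        new = scr_next_state(state, float(v), i, 0.0, float(k), params)
        if new.conducting != state.conducting:
            switches.append("on" if new.conducting else "off")
        state = new
        currents.append(scr_current(state, float(v), params))
    return v_path, np.array(currents), switches


class TestHysteresis:
    def test_iv_curve_is_two_valued(self):
        v, i, switches = quasi_static_sweep(PARAMS)
        # at 1.5 V (above the holding point, below threshold) the up and down
        # branches carry very different currents
        up = i[np.argmin(np.abs(v[:600] - 1.5))]
        down = i[600 + np.argmin(np.abs(v[600:] - 1.5))]
        assert down > 100 * up

    def test_switches_alternate_and_end_at_holding(self):
        v, i, switches = quasi_static_sweep(PARAMS)
        assert switches == ["on", "off"]
        # conducting episode ends only once i_ak <= i_hold
        conducting = i > PARAMS.i_hold
        v_off = v[600:][~conducting[600:]]  # blocking points on the down sweep
        i_at_off = (np.max(v_off) - PARAMS.v_on) / PARAMS.r_on
        assert i_at_off <= PARAMS.i_hold * 1.2


class TestAxon:
    def test_comparator_semantics(self):
        ax = AxonParams(i_trigger=1e-3, v_pulse=5.0)
        assert axon_output(0.0, ax) == 0.0
        assert axon_output(1e-3, ax) == 5.0           # boundary included
        assert axon_output(2e-3, ax) == 5.0           # saturating, not proportional


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(v_th_min=3.0),            # floor above nominal
        dict(r_on=1e8),                # r_on >= r_off
        dict(i_hold=0.0),
        dict(v_on=-0.1),
        dict(alpha_gate=-1.0),
    ],
)
def test_invalid_scr_params_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SCRParams(**kwargs)
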