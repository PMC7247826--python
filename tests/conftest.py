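import numpy as np
import pytest

import ucnsim as u
from ucnsim.battery import load_scenarios, run_battery


@pytest.fixture(scope="session")
def idealized_lif():
    """Instantaneous-discharge LIF idealization of the base circuit.

    Zero forward drop, 1-ohm conducting resistance and a huge blocking
    resistance make the reset level ~1e-5 V and the blocking dynamics
    indistinguishable from the pure RC leak, so the closed-form LIF period
    T = -tau * ln(1 - v_th / (A * r_leak)) applies.
    """
    scr = u.SCRParams(v_th0=2.0, v_th_min=0.5, i_hold=1e-5, r_off=1e12, r_on=1.0, v_on=0.0)
    circ = u.CircuitParams(c1=1e-9, r_leak=1e6)
    axon = u.AxonParams(i_trigger=1e-3, v_pulse=5.0)
    system = u.build_circuit("base", circ, scr, axon)
    tau = circ.c1 * circ.r_leak
    i_threshold = scr.v_th0 / circ.r_leak
    return system, tau, i_threshold


@pytest.fixture(scope="session")
def shipped_scenarios():
    return {s.scenario_id: s for s in load_scenarios()}


@pytest.fixture(scope="session")
def battery_report(tmp_path_factory):
    out = tmp_path_factory.mktemp("battery")
    return run_battery(out_dir=out), out


def make_pulse_trace(pulse_times, width=1e-4, v_pulse=5.0, t_end=None, dt=1e-5):
    """Synthetic trace with rectangular v_out pulses at given onset times."""
    t_end = t_end if t_end is not None else (max(pulse_times) + 10 * width if pulse_times else 1e-3)
    t = np.arange(0.0, t_end, dt)
    v_out = np.zeros_like(t)
    for t0 in pulse_times:
        v_out[(t >= t0) & (t < t0 + width)] = v_pulse
    return u.Trace(t=t, u=np.zeros_like(t), v_mem=np.zeros_like(t),
                   v_out=v_out, conducting=v_out > 0, dt_nominal=dt)
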