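{
  "scenario_id": "k_rebound_spike",
  "description": "Hyperpolarizing pulse through the differentiator: the release edge injects a depolarizing surge that fires one spike after the input ends.",
  "variant": "phasic",
  "protocol": "single",
  "expected_label": "rebound_spike",
  "duration_s": 0.01,
  "circuit": {
    "c1": 1e-09,
    "r_leak": 1000000.0,
    "r_in": 1000000.0,
    "c_in": 1.2e-09
  },
  "scr": {
    "v_th0": 2.0,
    "v_th_min": 0.5,
    "alpha_gate": 0.0,
    "i_hold": 1e-05,
    "r_off": 10000000.0,
    "r_on": 50000.0,
    "v_on": 0.8
  },
  "axon": {
    "i_trigger": 1.2e-05,
    "v_pulse": 5.0
  },
  "stimulus": {
    "kind": "negative_pulse",
    "t_on": 0.001,
    "amplitude": -1.2e-05,
    "width": 0.003
  },
  "rules": {
    "t_refractory": 5e-05
  }
}
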