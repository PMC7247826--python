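{
  "scenario_id": "j_accommodation",
  "description": "Differentiator input passes only the rate of change: silent for a slow ramp, fires for an abrupt step of the same amplitude.",
  "variant": "phasic",
  "protocol": "ramp_vs_step",
  "expected_label": "accommodation",
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
  "stimulus": [
    {
      "kind": "ramp",
      "t_on": 0.001,
      "slope": 0.0013333333333333333,
      "amplitude": 8e-06
    },
    {
      "kind": "step",
      "t_on": 0.001,
      "amplitude": 8e-06
    }
  ],
  "rules": {
    "t_refractory": 5e-05
  }
}
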