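{
  "scenario_id": "i_integrator",
  "description": "Two subthreshold pulses: integrated to a spike when close together, forgotten through the leak when far apart.",
  "variant": "base",
  "protocol": "pulse_pair",
  "expected_label": "integrator",
  "duration_s": 0.008,
  "circuit": {
    "c1": 1e-09,
    "r_leak": 1000000.0,
    "r_in": 1000000.0
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
      "kind": "paired_pulse",
      "t_on": 0.001,
      "amplitude": 5e-06,
      "width": 0.0004,
      "gap": 0.0001
    },
    {
      "kind": "paired_pulse",
      "t_on": 0.001,
      "amplitude": 5e-06,
      "width": 0.0004,
      "gap": 0.004
    }
  ],
  "rules": {
    "t_refractory": 5e-05
  }
}
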