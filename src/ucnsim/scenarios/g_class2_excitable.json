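{
  "scenario_id": "g_class2_excitable",
  "description": "Gate feedback lowers the breakover threshold once firing starts, making the onset bistable: the f-I curve jumps from zero to a finite rate (Hodgkin class 2).",
  "variant": "adaptive",
  "protocol": "fi",
  "expected_label": "class2_excitable",
  "duration_s": 0.015,
  "sample_dt_s": 1e-05,
  "circuit": {
    "c1": 1e-09,
    "r_leak": 1000000.0,
    "r_in": 1000000.0,
    "c_fb": 1e-09,
    "r_fb": 5000000.0,
    "beta_fb": 0.8
  },
  "scr": {
    "v_th0": 2.0,
    "v_th_min": 1.5,
    "alpha_gate": 1.0,
    "i_hold": 1e-05,
    "r_off": 10000000.0,
    "r_on": 50000.0,
    "v_on": 0.8
  },
  "axon": {
    "i_trigger": 5e-06,
    "v_pulse": 5.0
  },
  "stimulus": {
    "kind": "step",
    "t_on": 0.001,
    "amplitude": 2.9e-06
  },
  "amplitudes": [
    1.8e-06,
    2e-06,
    2.1e-06,
    2.35e-06,
    2.6e-06,
    2.9e-06
  ],
  "rules": {
    "t_refractory": 5e-05,
    "f_eps": 300.0,
    "f_jump": 400.0
  }
}
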