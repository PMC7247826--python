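{
  "scenario_id": "f_class1_excitable",
  "description": "Base circuit f-I curve: firing rate grows continuously from zero as the drive crosses rheobase (Hodgkin class 1).",
  "variant": "base",
  "protocol": "fi",
  "expected_label": "class1_excitable",
  "duration_s": 0.03,
  "sample_dt_s": 1e-05,
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
  "stimulus": {
    "kind": "step",
    "t_on": 0.001,
    "amplitude": 4.4e-06
  },
  "amplitudes": [
    2e-06,
    2.15e-06,
    2.21e-06,
    2.25e-06,
    2.4e-06,
    2.8e-06,
    3.5e-06,
    4.4e-06
  ],
  "rules": {
    "t_refractory": 5e-05,
    "f_eps": 300.0,
    "f_jump": 400.0
  }
}
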