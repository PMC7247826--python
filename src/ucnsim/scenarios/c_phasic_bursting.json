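{
  "scenario_id": "c_phasic_bursting",
  "description": "Stronger onset surge through a smaller series capacitor: a short burst, then silence.",
  "variant": "phasic",
  "protocol": "single",
  "expected_label": "phasic_bursting",
  "duration_s": 0.009,
  "circuit": {
    "c1": 1e-09,
    "r_leak": 1000000.0,
    "r_in": 1000000.0,
    "c_in": 8e-10
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
    "amplitude": 1.2e-05
  },
  "rules": {
    "t_refractory": 5e-05,
    "isi_intra": 0.0006,
    "isi_inter": 0.002
  }
}
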