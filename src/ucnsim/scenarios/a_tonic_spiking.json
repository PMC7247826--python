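{
  "scenario_id": "a_tonic_spiking",
  "description": "Sustained regular firing under a constant step at twice the rheobase drive.",
  "variant": "base",
  "protocol": "single",
  "expected_label": "tonic_spiking",
  "duration_s": 0.009,
  "circuit": {
    "c1": 1e-09,
    "r_leak": 1000000.0,
    "r_in": 1000000.0
  },
  "scr": {
    "v_th0": 2.0,
    "v_th_min": 0.5,
    "alpha_gate": 0.0,
    "i_hold": 5e-06,
    "r_off": 10000000.0,
    "r_on": 100000.0,
    "v_on": 0.8
  },
  "axon": {
    "i_trigger": 6e-06,
    "v_pulse": 5.0
  },
  "stimulus": {
    "kind": "step",
    "t_on": 0.001,
    "amplitude": 4.4e-06
  },
  "rules": {
    "t_refractory": 5e-05,
    "isi_intra": 0.0001,
    "isi_inter": 0.0002
  }
}
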