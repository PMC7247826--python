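{
  "scenario_id": "d_mixed",
  "description": "Capacitive surge plus a DC path just above rheobase: onset burst riding into slow tonic firing. Fast-recovery SCR (larger holding current) so the surge cannot latch it on.",
  "variant": "mixed",
  "protocol": "single",
  "expected_label": "mixed",
  "duration_s": 0.014,
  "circuit": {
    "c1": 1e-09,
    "r_leak": 1000000.0,
    "r_in": 200000.0,
    "c_in": 6e-09,
    "r_dc": 1000000.0
  },
  "scr": {
    "v_th0": 2.0,
    "v_th_min": 0.5,
    "alpha_gate": 0.0,
    "i_hold": 3e-05,
    "r_off": 10000000.0,
    "r_on": 10000.0,
    "v_on": 0.8
  },
  "axon": {
    "i_trigger": 1.2e-05,
    "v_pulse": 5.0
  },
  "stimulus": {
    "kind": "step",
    "t_on": 0.001,
    "amplitude": 2.2e-05
  },
  "rules": {
    "t_refractory": 5e-05,
    "isi_intra": 0.0008,
    "isi_inter": 0.0015
  }
}
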