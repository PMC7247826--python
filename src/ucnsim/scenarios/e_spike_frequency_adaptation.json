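{
  "scenario_id": "e_spike_frequency_adaptation",
  "description": "Spike-triggered feedback accumulates a shunt conductance on the membrane; interspike intervals lengthen progressively under constant drive.",
  "variant": "adaptive",
  "protocol": "single",
  "expected_label": "spike_frequency_adaptation",
  "duration_s": 0.011,
  "circuit": {
    "c1": 1e-09,
    "r_leak": 1000000.0,
    "r_in": 1000000.0,
    "c_fb": 1e-09,
    "r_fb": 20000000.0,
    "beta_fb": 0.2,
    "g_shunt": 2e-07
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
  "rules": {
    "t_refractory": 5e-05,
    "isi_intra": 0.0001,
    "isi_inter": 0.0002
  }
}
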