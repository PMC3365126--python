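{
  "geometry": "sphere",
  "mechanical": {
    "K": 0.24,
    "eta": 1.1e-05,
    "nu": 0.7,
    "r_c": 5e-06
  },
  "electrical": {
    "tau_e": 5e-06,
    "C_sp": 0.01
  },
  "coupling": {
    "alpha_Csp": -0.04999999999999999
  }
}
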