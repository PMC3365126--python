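{
  "geometry": "cylinder",
  "mechanical": {
    "C11": 0.075,
    "C12": 0.07,
    "C22": 0.19,
    "eta": 1.1e-05,
    "nu": 0.7,
    "r_c": 5e-06
  },
  "electrical": {
    "tau_e": 5e-06,
    "C_sp": 0.01
  },
  "coupling": {
    "alpha1_Csp": -0.1,
    "alpha2_Csp": 0.03
  }
}
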