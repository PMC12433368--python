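{
  "name": "P_beta",
  "intercept": -13.195,
  "coefficients": {
    "dT2_bT2": 105.132,
    "aT3_bT1": 0.388
  }
}
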