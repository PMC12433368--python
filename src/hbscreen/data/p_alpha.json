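{
  "name": "P_alpha",
  "intercept": 1.771,
  "coefficients": {
    "zT8_bT2": 30.444,
    "aT1_bT1": -1.030
  }
}
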