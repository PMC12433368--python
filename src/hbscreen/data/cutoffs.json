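{
  "p_alpha_screen": 0.33,
  "p_beta_screen": 0.13,
  "p_alpha_alpha0": 0.66,
  "p_alpha_sea": 0.87,
  "p_alpha_hbh": 0.88,
  "variant_thresholds": {
    "Hb S": 0.0,
    "Hb E": 0.0,
    "Hb D-Los Angeles": 0.0,
    "Hb G-Coushatta": 2.19,
    "Hb Watford": 0.0,
    "Hb Nanchang": 0.0,
    "Hb Hekinan II": 0.0
  }
}
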