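{
  "alphaT1": 2.0,
  "alphaT3": 10.0,
  "betaT1": 5.0,
  "betaT2": 5.0,
  "gammaT10": 0.5,
  "deltaT2": 0.2,
  "zetaT8": 0.1
}
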