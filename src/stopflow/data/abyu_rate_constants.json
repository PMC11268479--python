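{
  "k1": 0.88,
  "k1r": 3.41,
  "k2": 0.36,
  "k2r": 0.71,
  "k3": 0.00057,
  "k3r": 0.0069,
  "k4": 1.37,
  "k4r": 0.9,
  "k5": 100.0,
  "k6": 0.12,
  "kspont": 0.00125
}
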