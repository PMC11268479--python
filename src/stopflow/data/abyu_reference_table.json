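{
  "k1": {"value": 0.88, "std": 0.03, "units": "uM^-1 s^-1"},
  "k1r": {"value": 3.41, "std": 0.71, "units": "s^-1"},
  "k2": {"value": 0.36, "std": 0.46, "units": "uM^-1 s^-1"},
  "k2r": {"value": 0.71, "std": 0.62, "units": "s^-1"},
  "k3": {"value": 0.00057, "std": 3.8e-05, "units": "uM^-1 s^-1", "approximate": true},
  "k3r": {"value": 0.0069, "std": 0.0019, "units": "s^-1", "approximate": true},
  "k4": {"value": 1.37, "std": 2.38, "units": "s^-1"},
  "k4r": {"value": 0.9, "std": 2.29, "units": "s^-1"},
  "k6": {"value": 0.12, "std": 0.05, "units": "s^-1", "approximate": true},
  "kspont": {"value": 0.00125, "std": 1.7e-05, "units": "s^-1"},
  "K1": {"value": 3.86, "std": 0.94, "units": "uM"},
  "K2": {"value": 1.97, "std": 4.24, "units": "uM"},
  "K4": {"value": 0.66, "std": 2.81, "units": "dimensionless"},
  "Kapp": {"value": 1.3, "std": 8.4, "units": "uM"}
}
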