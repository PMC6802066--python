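{
  "beta0": {"mean": 3.53, "sd": 1.62},
  "a": {"mean": 0.14, "sd": 1.57},
  "b": {"mean": 3.49, "sd": 1.76},
  "beta_elevation": {"mean": -0.29, "sd": 0.27},
  "beta_precipitation": {"mean": 1.59, "sd": 0.97},
  "beta_roughness": {"mean": 0.00, "sd": 0.29},
  "beta_forest": {"mean": 0.46, "sd": 0.34}
}
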