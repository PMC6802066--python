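{
  "beta0": {"mean": 0.15, "sd": 1.15},
  "a": {"mean": -0.68, "sd": 1.52},
  "b": {"mean": 4.32, "sd": 1.94},
  "beta_elevation": {"mean": -0.52, "sd": 0.29},
  "beta_precipitation": {"mean": -0.41, "sd": 0.30},
  "beta_roughness": {"mean": -0.08, "sd": 0.21},
  "beta_forest": {"mean": 0.64, "sd": 0.26}
}
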