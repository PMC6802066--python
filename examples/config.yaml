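# Fitting configuration for `occutrend fit` / `occutrend all`.
mcmc:
  chains: 3
  burnin: 5000       # per chain
  retained: 10000    # pooled across chains, after thinning
  thin: 3
  seed: 11
model:
  interaction: false       # precipitation x z(t-1) transition term
  share_transitions: false # pool a_t, b_t across transitions
prior:
  vague_scale: 10.0
  scale_convention: variance   # sd | variance | precision
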