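# occutrend

Bayesian multi-season (dynamic) occupancy modeling for regional wildlife
trend monitoring, built around the autologistic parameterization and
empirically informed prior updating between monitoring periods.

The motivating use case is grid-based acoustic bat monitoring: a region is
divided into 100-km² cells, a spatially balanced subset of cells is visited
a few nights each summer, and each visit yields a detection (1) or
nondetection (0) for a species. Because a night's nondetection does not
mean absence, occupancy models separate the probability a cell is occupied
(Ψ) from the probability of detecting the species on one visit given
occupancy (p). Tracking Ψ across years gives a conservative, region-wide
proxy for population trend without ever counting individuals.

## The model

For sites *i* = 1..*n*, seasons *t* = 1..*T*, visits *j* = 1..*J*:

- Initial occupancy: `z(i,1) ~ Bernoulli(Ψ₁ᵢ)`,
  `logit(Ψ₁ᵢ) = β₀ + β₁Forestᵢ + β₂Elevationᵢ + β₃Precipᵢ + β₄Roughᵢ`
- Transitions (autologistic): `z(i,t) | z(i,t−1) ~ Bernoulli(π_ti)`,
  `logit(π_ti) = a_t + b_t·z(i,t−1) + Σ β_k x_ki`
- Detection (false negatives only): `y_j(i,t) | z(i,t) ~ Bernoulli(p_itj·z(i,t))`,
  `logit(p_itj) = α₀ + α₁·date_itj`

Derived quantities: persistence `ϕ_t = logit⁻¹(a_t + b_t)`, colonization
`γ_t = logit⁻¹(a_t)`, the recursive trajectory
`Ψ_t = Ψ_{t−1}ϕ_t + (1 − Ψ_{t−1})γ_t`, and the occurrence growth rate
`λ = Ψ_T / Ψ₁` (reported both as the total over the study period and as its
annualized geometric mean). λ below 1, with a 95% credible interval
excluding 1, is the model's evidence of region-wide decline.

Priors are independent Normals. A previous monitoring period's posterior
means and SDs can be carried forward as priors for the occupancy-level
parameters (the "scaffolding" workflow); detection parameters always get
vague Normal(0, variance 10) priors because survey methodology rarely
carries over. Posterior sampling uses a componentwise slice sampler on the
latent-state-marginalized likelihood (a two-state forward recursion per
site), with latent z recovered per retained draw by forward-filtering
backward-sampling.

## Worked example

```python
import occutrend as ot

data, truth = ot.generate_dataset(ot.ScenarioConfig(seed=2, preset="declining"))
priors = ot.vague_priors(ot.param_names(data.n_seasons - 1))
config = ot.McmcConfig(seed=3, n_chains=2, n_burnin=500, n_retained=1500, thin=2)
draws = ot.fit_model(data, priors, config)
print(ot.summarize_posterior(draws).loc[["psi[1]", "psi[3]", "lambda_annual"]])
```

which prints (see `examples/02_fit_and_trend.py` for the full script):

```
                mean     sd   q2.5  q97.5
parameter
psi[1]         0.904  0.039  0.827  0.971
psi[3]         0.643  0.049  0.547  0.739
lambda_annual  0.844  0.033  0.778  0.906
```

The simulated region declined at a true annual rate of 0.86 (occupancy
0.87 → 0.64 over three seasons); the fitted annual λ of 0.84 with interval
[0.78, 0.91] excludes 1, correctly flagging the decline despite per-visit
detection of only ~0.4.

The `examples/` directory holds one narrative script per capability:
survey simulation, trend fitting, informed-prior updating, and evaluation
(posterior AUC, Moran's I residual profile, frame-wide prediction).

A thin CLI wraps the same functions for shell use:

```bash
occutrend --outdir run all --scenario scenario.yaml --seed 1
```

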