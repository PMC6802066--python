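# Methods

## Model

`occutrend` implements the autoregressive (autologistic) parameterization
of the multi-season occupancy model. The latent occupancy state of site
*i* in season *t* is `z(i,t) ∈ {0,1}`. Season 1 follows
`Bernoulli(Ψ₁ᵢ)` with a logistic regression on four standardized site
covariates (forest cover, elevation, precipitation, topographic
roughness). Later seasons follow a two-state Markov chain whose transition
probability shares the covariate effects and adds a season-specific
intercept `a_t` and autologistic offset `b_t·z(i,t−1)`:
persistence `ϕ_t = logit⁻¹(a_t + b_t)` and colonization
`γ_t = logit⁻¹(a_t)` are derived, not free, parameters. Detection is a
Bernoulli thinning of `z` with a per-visit logistic date effect and no
false positives: a detection at an unoccupied site has probability zero,
which presumes upstream species-identification has been cleaned to remove
misidentifications. Missing visits are skipped in the detection product,
i.e. treated as missing at random given `z`.

An optional transition term `β₅·Precipᵢ·z(i,t−1)` (an
environment-by-persistence interaction) can be enabled; it is off by
default. Season-specific `a_t, b_t` are the default; a
`share_transitions` flag pools them for short series.

The trend metric is the occurrence growth rate `λ = Ψ_T/Ψ₁` evaluated at
average covariates (all zeros after standardization). Both the total and
the annualized value `λ_total^(1/(T−1))` are always computed and reported,
because a λ printed for a multi-year window is ambiguous between the two
conventions; conclusions should be read from whichever matches the
reporting period, and both are summarized per draw (never from summarized
Ψ means, which would incur Jensen-gap bias — a test asserts the gap).

## Inference

The sampler works on the z-marginalized likelihood: for each site the sum
over latent sequences is computed by a two-state forward recursion in log
space (−∞ propagates cleanly through `logaddexp`), so the posterior over
the ~11 regression-scale parameters is low-dimensional and smooth.
Sampling uses a componentwise stepping-out slice sampler (Neal 2003).
Bracket widths start at `min(prior SD, 3)` and are re-tuned every 200
burn-in iterations to 2.5× the recent posterior SD; slice sampling is
rejection-free and insensitive to the width within a factor of a few, so
this adaptation only affects efficiency, not correctness (and it stops at
the end of burn-in). Latent states are recovered per retained draw by
forward-filtering backward-sampling from their exact full conditional,
giving joint `(θ, z)` posterior draws equivalent to a Gibbs scheme.

Defaults mirror a conventional three-chain budget: 5,000 burn-in
iterations, 10,000 retained draws pooled across 3 chains, thinning 3. The
retained count is interpreted as a pooled total (≈3,334 per chain). Chains
receive independent substreams spawned from the single user seed;
identical configurations reproduce identical draws. Initial values are the
prior means jittered by N(0, 0.1²) per chain; because the likelihood is
marginalized over z, every finite parameter vector has positive posterior
density, so no special-case initialization is needed.

Convergence is monitored with the split-chain potential scale reduction
factor (each chain halved, classic between/within variance ratio), flagged
at `|R̂ − 1| ≥ 0.1`. A cross-check test verifies agreement with
`arviz.rhat(method="split")` to 1e-10. The split variant is slightly more
conservative than the unsplit original that the 0.1 criterion was
historically attached to.

Validation of the sampler is by independent oracles rather than by trust
in the algorithm: exact agreement of the forward recursion with 2^T
enumeration; agreement of posterior means with 2-D grid quadrature on an
intercept-only reduction; simulation-based calibration (200 replicates,
uniform rank histograms for all occupancy-level parameters); and 95%
interval coverage at realistic generating values.

## Priors and period-to-period scaffolding

Vague priors are Normal(0, 10) interpreted as **variance** 10
(SD ≈ 3.16): the BUGS-style precision-0.1 idiom. An SD of 10 on the logit
scale would place mass far outside any plausible probability and would not
regularize; the convention is switchable (`sd`, `variance`, `precision`)
for users whose conventions differ.

Informed priors take a previous period's posterior (mean, SD) per
occupancy-level parameter [β, a, b] and use them as Normal priors for the
new fit. A single (a, b) summary pair is applied to every new-period
transition. Detection-level parameters always get vague priors, since
detector hardware and identification workflow change between periods.
Bundled tables for two species (hoary bat, little brown bat) reproduce a
published 2010 monitoring posterior; the table rows labeled with the
transition parameters map to `a` (colonization intercept) and `b`
(autologistic offset) — under that mapping the implied dynamics are
ϕ ≈ 0.97, γ ≈ 0.34, matching the expected near-1 persistence / low
colonization background for long-lived, site-faithful bats.

`posterior_to_prior` closes the loop (≥100 retained draws required for
stable moments; degenerate posteriors rejected). A property test verifies
that informed priors tighten occupancy-level posteriors on average, and a
wash-out test that a much wider prior leaves the posterior unchanged for
likelihood-identified parameters. The autologistic offset `b` is the known
exception: when persistence is near 1 the likelihood is flat in `b` above
a few units, so `b` never fully escapes its prior regardless of sample
size. This is a structural identifiability limit of the parameterization,
not a sampler artifact.

## Evaluation

**Posterior AUC** follows the internal-validation convention: for each
retained draw, the draw's own site-level `Ψ_{i,year}` scores the draw's
own latent `z_{i,year}`; the rank/Mann-Whitney AUC (ties ½) is summarized
over draws. Scoring raw detections instead is available behind a flag but
conflates detection with occupancy. Draws whose z is single-class are
skipped and counted.

**Moran's I** probes residual spatial structure the covariates failed to
absorb. Residuals are occupancy-level, `z⁽ᵐ⁾ᵢ − Ψ⁽ᵐ⁾ᵢ` per draw, with
binary weights `w_ij = 1` iff `0 < d(i,j) ≤ threshold` on projected km
coordinates (sites exactly at the threshold count; default ladder
10–50 km in 10-km steps, 10 km = adjacent cells). The posterior-mean I per
threshold is reported with a one-sided (clustering) permutation p computed
on the posterior-mean residual vector with 999 seed-controlled
permutations. Calibration tests assert the −1/(n−1) null mean and
super-uniformity of the permutation p under iid residuals.

**Prior sensitivity** compares the two regimes parameter-wise (means, SDs,
SD ratio, agreement of the 95%-interval position relative to zero) and
exports tidy prior/posterior density curves for plotting.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
with known ground truth:

- **Frame**: a regular 10-km grid (default 4,500 cells ≈ the real frame).
  Forest cover declines monotonically west→east plus smooth noise;
  precipitation is constructed by exact orthogonalization to hit the
  requested forest–precipitation correlation (default 0.7) before clipping
  to physical units; elevation and roughness are independent smooth
  Gaussian fields.
- **Site selection**: recursive quadrant-stratified sampling stands in for
  the GRTS master-sample ordering — it reproduces the spatial balance
  (verified by a mean nearest-neighbor-distance test) without the
  hierarchical address machinery, which the downstream model never uses.
  A configurable fraction (default 20% of 190 sites) is drawn uniformly
  from a designated 241-cell legacy pool instead, mimicking re-enrolled
  earlier-period cells.
- **Dynamics presets**: `hoary-2010` / `little-brown-2010` use the
  bundled period-1 posterior means verbatim. `stable` uses the hoary-like
  dynamics with initial occupancy at the stationary point
  `γ/(γ+1−ϕ)` so the true λ is exactly 1. `declining` starts at Ψ₁ = 0.87
  and solves for the persistence that yields a true annual λ of 0.86
  (the published decline estimate), keeping γ at its background value.
- **Detection**: visit dates uniform over June 1–September 30,
  standardized with the same population-SD convention as real data;
  default α₀ = logit(0.4), α₁ = 0.3, spanning per-visit detection
  ≈ 0.25–0.55 across the season. Unoccupied site-seasons never produce
  detections. An optional missingness rate reproduces ragged designs
  (each site retains at least one observed visit); a single-visit design
  triggers an identifiability warning.

What the generator does **not** emulate: spatially autocorrelated
occupancy beyond what the smooth covariate surfaces induce, survey-method
or duration heterogeneity, false-positive contamination, and
call-level acoustic structure. Passing tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to their violation in field data.

## Numerical choices and problem sizes

- All likelihood accumulation is in log space; impossible configurations
  return −∞ rather than raising.
- Covariate standardization uses the population-SD convention and the
  constants are stored with the dataset, so frame-wide prediction applies
  the identical transform; passing raw frame columns without the stored
  scaler is an error.
- Quantiles are equal-tailed; posterior SDs use ddof = 1.
- Test fits use reduced MCMC budgets (hundreds of burn-in iterations,
  ~500–1,500 retained draws) chosen from mixing measurements of the slice
  sampler — its componentwise autocorrelation times on these posteriors
  are a few iterations, so these budgets give Monte Carlo errors well
  inside the assertion tolerances. The full default budget is exercised
  once (convergence criterion test, and `scripts/acceptance.py`).
- SBC uses Normal(0,1) priors over all parameters, 200 replicates, 99
  retained draws per fit (ranks binned into 10 bins, χ² at α = 0.01 per
  parameter).

## Known limitations

- `b_t` is only partially identified when ϕ → 1 (see above).
- The AUC convention (labels = same-draw z) makes AUC an internal
  consistency measure, optimistic relative to out-of-sample discrimination.
- The permutation p for Moran's I is computed on the posterior-mean
  residual vector; fully propagating posterior uncertainty through the
  permutation null would roughly square the cost for little change on
  these data sizes.
- No model selection (WAIC/DIC), spatial random effects, or multi-species
  joint modeling; the false-positive-free detection model is an input
  assumption, not something the package can verify.
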