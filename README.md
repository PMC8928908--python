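# spatocc

Single-season site-occupancy models with **spatially correlated detections**
along transect segments, for sign-survey data.

## The problem

Sign surveys for elusive mammals (bears, small carnivores, ungulates) often
replace repeat visits with *spatial* replicates: one transect per sampling
grid, split into contiguous segments, each scored 1/0 for fresh sign.
Standard single-season occupancy models (MacKenzie-style) treat replicates as
independent given occupancy — untenable for adjacent 200-m segments, where an
animal's local presence carries over from one segment to the next.  Ignoring
that correlation biases both the occupancy estimate ψ and its uncertainty.

`spatocc` implements the correlated-detection extension (Hines-style): within
an occupied site, local presence `z_k` on segment `k` follows a first-order
Markov chain

```
Pr(z_1 = 1) = π,   Pr(z_k = 1 | z_{k-1} = 0) = θ⁰,   Pr(z_k = 1 | z_{k-1} = 1) = θ¹,
```

and detection on a segment is Bernoulli(p) given local presence (impossible
without it).  The site likelihood is

```
Pr(h_i) = ψ_i · F(h_i; π, θ⁰, θ¹, p_i) + (1 − ψ_i) · I[h_i has no detection],
```

with `F` computed by the two-state forward algorithm; missing segments
contribute no information but the chain still transitions.  ψ and p carry
logit-linear covariate models; π, θ⁰, θ¹ are free logit-scale parameters
(π can instead be fixed or tied to the chain's stationary value).

Around that likelihood the package provides, in the statsmodels idiom
(`OccupancyModel(...).fit() → OccupancyResults`):

- multi-start quasi-Newton ML estimation with a Newton polish, finite-difference
  variance–covariance, delta-method real-scale estimates and per-site ψ̂;
- AIC ranking with Akaike weights, the two-step detection-first/occupancy-second
  selection workflow with stepwise-additive covariate search, and AIC-weighted
  model averaging with unconditional SEs;
- parametric-bootstrap goodness of fit with the overdispersion factor ĉ;
- a synthetic-data generator that mirrors the assumed generative process
  (covariate-driven occupancy, Markov availability, segment-level covariate
  indicators aggregated to grid proportions, missing segments) and a
  simulate→fit→summarise recovery harness;
- CSV I/O for detection histories and covariates, covariate construction from
  segment records, z-scaling, collinearity screening, and a `spatocc` CLI
  (`simulate`, `fit`, `select`, `average`, `gof`, `predict`, `report`).

## Worked example

Simulate a 45-grid × 20-segment survey from the default conditions
(ψ ≈ 0.7, p = 0.25, θ⁰ = 0.3, θ¹ = 0.7, π = 0.45) and fit the
correlated-detection null model:

```python
from spatocc import ModelSpec, OccupancyModel
from spatocc.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_sites=45, n_segments=20, seed=3))
res = OccupancyModel(ds.y, spec=ModelSpec()).fit(n_starts=10, seed=0)
print(res.summary())
```

```
Occupancy model fit
  model:     psi(.),th0(),th1(),p(.),th0pi()
  sites:     45   segments: 20
  logLik:    -273.0816   K: 5   AIC: 556.16
  converged: True (|grad| = 4.02e-08, starts = 10)

                      beta       se      lci      uci
psi:(Intercept)      1.226    0.565    0.119    2.334
p:(Intercept)       -0.611    0.413   -1.420    0.198
th0:(Intercept)     -1.826    0.382   -2.575   -1.078
th1:(Intercept)      1.107    0.652   -0.171    2.385
th0pi:(Intercept)   -0.136    0.696   -1.500    1.228

Real-scale estimates (at covariate means):
  psi      0.773  SE  0.099  95% CI [0.579, 0.967]
  p        0.352  SE  0.094  95% CI [0.167, 0.536]
  theta0   0.139  SE  0.046  95% CI [0.049, 0.228]
  theta1   0.752  SE  0.122  95% CI [0.513, 0.990]
  pi       0.466  SE  0.173  95% CI [0.127, 0.806]
```

The real-scale block reads: an estimated 77% of grids are occupied
(truth 0.70, with the wide small-sample CI typical of 45 sites); given
occupancy, sign is locally present on a first segment with probability 0.47
and persists between adjacent segments with probability 0.75 (starts afresh
with 0.14); a surveyed segment with local presence yields a detection with
probability 0.35 (truth 0.25).  The standard independent-replicate model
(`ModelSpec(correlated=False)`) fits the same data 9.8 AIC points worse
(AIC 565.97), the usual signature of segment-to-segment correlation in sign
surveys.

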