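# Methods

## Model

A survey consists of `n` sites (grid cells); site `i` is occupied with
probability ψ_i, modelled as logit ψ_i = x_iᵀβ on z-scaled site covariates.
Within an occupied site, the transect is split into `K` contiguous segments
and the species' *local presence* z_k on segment k follows a two-state
first-order Markov chain: Pr(z₁ = 1) = π, Pr(z_k = 1 | z_{k−1} = 0) = θ⁰,
Pr(z_k = 1 | z_{k−1} = 1) = θ¹.  Detection y_k on a surveyed segment is
Bernoulli(p_{ik}) when z_k = 1 and impossible when z_k = 0; logit p carries
its own covariate model (site-level by default, per-segment optionally).
The site likelihood mixes the occupied and unoccupied branches:

Pr(h_i) = ψ_i · F(h_i) + (1 − ψ_i) · 1[h_i contains no detection],

where F is the probability of the observed segment outcomes given
occupancy, computed with the two-state forward algorithm (O(K) per site).
Unsurveyed segments contribute emission factor 1 while the chain still
transitions — missingness is treated as a design artifact (areas that could
not be surveyed), conditioned on rather than modelled.  Setting
θ⁰ = θ¹ = π = 1 recovers the standard independent-replicate model exactly,
and θ⁰ = θ¹ = π = θ with constant p collapses to the standard model with
detection θ·p; both identities are enforced in tests against a brute-force
enumeration over all 2^K latent sequences.

All probability parameters use the logit link.  π is a free parameter by
default — that convention is what makes the parameter counts of the
reference model structures come out at K = 14 (global 6-covariate ψ,
3-covariate p) and K = 9 (univariate ψ) — with `pi_mode="stationary"`
(π = θ⁰/(1 + θ⁰ − θ¹)) and `pi_mode="fixed"` as options.

## Estimation

The negative log likelihood is minimised by L-BFGS-B from `n_starts`
(default 10) starting points — zero on the link scale, then seeded N(0, 1)
jitter — followed by a damped-Newton polish on central finite differences
(gradient step h = 1e−6, Hessian h = 1e−5).  The polish matters: with
finite-difference gradients L-BFGS stalls around ‖∇‖ ≈ 1e−3–1e−4, while
the convergence contract requires ‖∇‖ < 1e−6 plus a positive-definite
Hessian.  The variance–covariance matrix is the inverse Hessian; a non-PD
Hessian marks the fit non-converged rather than silently pseudo-inverting.
Real-scale parameters within 1e−4 of 0 or 1 raise boundary flags — at the
45-site study scale a ψ→1 ridge (compensated by low availability) is an
occasional genuine optimum and is reported as such.

Real-scale estimates use the delta method: for a linked parameter with
linear predictor η, se = value·(1 − value)·√(xᵀΣx), with 95% intervals
value ± 1.96·se truncated to [0, 1] (symmetric on the probability scale,
matching how such tables are conventionally printed).  Coefficient CIs are
±1.96·SE on the link scale.  Delta-method SEs are validated against
Monte-Carlo propagation (10⁵ draws) in the test suite.

## Model selection and averaging

AIC = −2ℓ + 2K throughout (no small-sample correction).  Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) and model likelihoods exp(−Δ_i/2); ranking
ties break toward smaller K, then input order.  The two-step workflow first
ranks detection structures under a global (all-covariate) occupancy model,
then fixes the best detection structure and searches occupancy structures
stepwise: null and all univariate models first, then greedy addition of the
covariate that most decreases AIC, stopping at the first non-improvement
(strict decrease, any amount).  The null model under the second-best
detection structure joins the candidate set, mirroring common practice when
two detection models are near-tied.  Model averaging spans *all* fitted
second-step models: the ψ summary each model contributes is the unweighted
mean of its site-level ψ̂ (the natural "proportion of area occupied"
scalar), p is evaluated at covariate means (scaled zero), and the
unconditional SE is Σ w_i·√(se_i² + (θ̂_i − θ̄)²), folding between-model
spread into within-model variance.

## Goodness of fit

Model adequacy uses a parametric bootstrap: B datasets (default 1000) are
simulated from the fitted model with the original covariates and
missingness pattern, refitted under the same specification (started at the
parent MLE), and a Pearson statistic recomputed at each refit's own MLE.
p = (1 + #{X²_boot ≥ X²_obs})/(B + 1); ĉ = X²_obs / mean(X²_boot).

Two statistics are available.  `pearson_chisq_histories` follows the
classical construction — cohorts of sites sharing a missingness pattern and
covariate profile, cells = unique observed histories plus one pooled
complement.  With K = 20 segments that statistic is unusable in practice:
nearly every history is unique, expected cell counts fall below 1e−6, and
the statistic's distribution becomes so heavy-tailed that ĉ is dominated by
noise (null simulations gave median ĉ ≈ 0.2).  The bootstrap therefore
defaults to a *half-transect joint count* statistic: sites are
cross-classified by their number of detections in the first and second
halves of the transect, expected cell frequencies come from an exact
dynamic program over (chain state, count pair) — which also covers the
standard model via the saturated-chain limit — and cells are pooled in
ascending lexicographic order until each pooled cell has expectation ≥ 2.
The two-way margin keeps enough degrees of freedom for ĉ to centre near 1
and retains sensitivity to the between-segment correlation structure.
Under null simulations at the calibration scale (100 sites × 20 segments,
B = 100) this gives rejection rates of 4–8% at nominal 5% and median
ĉ ≈ 0.99–1.04 across independent seed families.

One structural caveat: with exchangeable sites and no covariates the
distribution of detection histories depends on ψ only through its mean, so
pure site-to-site heterogeneity in ψ is *unidentifiable* and no GoF
statistic can flag it; heterogeneity in detection probability, by contrast,
is picked up strongly (designed-overdispersion test: ĉ ≈ 7).

## Synthetic data

The generator reproduces the assumed generative process at the study's
design: 45 grids × 20 segments of 200 m by default, ψ ≈ 0.7 (logit-scale
intercept 0.8473), p = 0.25, (θ⁰, θ¹, π) = (0.3, 0.7, 0.45) — values chosen
to match the scale of sign-survey data for a wide-ranging, hard-to-detect
bear.  Covariates are either continuous standard-normal site scores
(remote-sensing-like) or per-segment Bernoulli indicators aggregated to the
proportion of observed segments with presence (termite-mound-like), then
z-scaled; detection can optionally be driven by the raw per-segment
indicators (`p_level="segment"`), mimicking a food resource that raises
sign density locally.  Missing segments are injected uniformly at random,
or as contiguous trailing blocks per site (`missing_mode="block"`) to mimic
areas outside jurisdiction; at least one segment per site always remains.

What passing recovery tests do *not* show about real data: covariate fields
here are spatially unstructured, occupancy has no residual heterogeneity
beyond the modelled covariates, and the availability chain is exactly
first-order — real sign decay/deposition processes are messier, so
real-data standard errors should be read as lower bounds on honest
uncertainty.

## Problem sizes and numerical choices

The recovery study runs 100 replicates of 1000 sites × 20 segments
(median absolute bias < 0.03 and 91–97% CI coverage on every real
parameter); the GoF calibration uses 100 meta-replicates of 100 sites with
B = 100; the validation of the forward recursion enumerates all 2^K latent
paths for K ≤ 12.  The likelihood kernels are numba-compiled with per-step
rescaling against underflow (irrelevant at K = 20 but cheap insurance for
long transects).  Bootstrap refits use a single start at the parent MLE
without the Newton polish — the statistic, not the vcov, is needed there.
Degenerate inputs are contract-checked: empty files, non-binary tokens,
all-missing sites, constant covariate columns and probability parameters
outside [0, 1] raise validation errors naming the offender; a detection at
a segment where the model says p = 0 yields likelihood 0 (−∞ log), not an
exception.

## Known limitations

No multi-season dynamics, multi-species interactions or abundance-induced
heterogeneity; no AICc/QAIC re-ranking from ĉ (reported only); Wald/delta
intervals rather than profile likelihood, so small-sample intervals near
boundaries are approximate; segment-level detection covariates are
supported in the likelihood but not threaded through the two-step selection
workflow, which operates on site-level covariates.
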