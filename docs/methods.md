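# Methods

## Scope and model families

`frfit` infers a predator's functional response — the relationship between
the density of prey offered and the number eaten per unit time — from arena
predation trials in which eaten prey are not replaced. The experimental
template is a Petri-dish assay: one predator, focal-prey densities
N0 ∈ {5, 10, 25, 50, 80}, six replicate arena-days per density, optional
alternative prey offered alongside (0/5/25/80 individuals), two contexts
(non-parasitized focal prey, or parasitized focal prey so that eating them
constitutes intraguild predation), and 24 h of exposure (T = 1 day).

Four families are implemented:

* **Holling type II (disc equation)**, `Ne = aNT / (1 + ahN)` — no
  depletion; kept for completeness and for teaching comparisons.
* **Rogers type II (random-predator equation)** — the depletion-corrected
  type II, defined implicitly by `Ne = N0 (1 − exp(a (h Ne − T)))` and
  solved in closed form with the principal Lambert-W branch,
  `Ne = N0 − W(a h N0 e^{−a(T − h N0)}) / (a h)`.
* **Flexible-exponent (generalized) response** — the Rogers equation with a
  density-dependent attack rate `a = b N0^q`. `q = 0` recovers type II
  exactly (`a = b`), `q = 1` is classic type-III density dependence, and
  intermediate/larger `q` interpolates beyond both.
* **Hassell type III** — the Rogers equation with the saturating attack
  function `a_eff = (d + b N0) / (1 + c N0)`.

Parameter units: `a` per day; `h` days per prey; `T` days; `q`
dimensionless; `b` per day per prey^q (flexible family) or per day per prey
(Hassell); `c` per prey; `d` per day. The maximum feeding rate is
`MFr = 1/(hT)` (prey/day), reported rounded to the nearest integer.

## Numerical solution of the implicit equation

The Lambert-W closed form is used wherever its argument is representable in
double precision; one Newton step on
`f(Ne) = Ne − N0(1 − exp(a(hNe − T)))` then drives the implicit-equation
residual to machine level (the test suite checks |residual| < 1e−10 and
agreement within 1e−8 with an independent damped fixed-point iteration over
a randomized parameter grid). When `a·h·N0` exceeds ≈700 the W argument
overflows; there the solver switches to bisection on `f`, which is strictly
increasing (`f' > 1`) with a unique root in `[0, min(N0, T/h)]`, an interval
on which the exponent is non-positive so evaluation cannot overflow. Results
are clamped to `[0, N0]`. A note on fixed-point alternatives: the undamped
map oscillates, and a half-damped map still diverges once
`a·h·(N0 − Ne) ≫ 1`; a contraction requires damping like
`1/(1 + a h N0)`, which is what the test-suite oracle uses. Bisection was
chosen for the production fallback because its cost is bounded and
parameter-independent.

Degenerate inputs: `a = 0` or `N0 = 0` return 0; `h = 0` uses the closed
form `N0(1 − e^{−aT})`; `N0 = 0` with `q < 0` returns 0 rather than raising.

## Likelihood, fitting and standard errors

Counts are modelled binomially: `ne ~ Binomial(n0, Ne_hat/n0)`, predicted
probabilities clipped to `[1e−9, 1 − 1e−9]`. This is the natural likelihood
for a depletion design where each offered prey is independently at risk; it
is also exactly the distribution the default synthetic generator draws
from, which makes estimator-recovery tests well-posed.

Optimization is Nelder-Mead on `log a` / `log b` / `log c` / `log h` (with
`q` free and unconstrained, since published generalized fits report `q`
intervals crossing zero). Starting values follow the field convention:
`a = b = 1`, `h = 1/Fmax` with `Fmax` the mean consumption at the highest
density, `q = 0`; the flexible family additionally starts from `q = 1` and
`q = 2` with `b` rescaled so the median-density attack rate is ~1 (the
`q = 0` start alone can strand the optimizer in a local optimum when the
truth is strongly sigmoidal), and the Hassell family starts from
`b = 1/median(N0)` with small `c`. If no start yields a finite optimum, up
to 10 multiplicatively jittered (×U(0.5, 2)) restarts are tried from a
seeded generator, keeping fits fully reproducible. Invalid parameter
regions return +inf rather than raising.

Standard errors come from the inverse numerical Hessian of the negative
log-likelihood in the transformed space, delta-methoded back to the natural
scale; Wald `z = estimate/SE` with two-sided normal p-values. A fit is
reported `converged` only when the optimizer succeeded *and* the Hessian is
positive definite. `AIC = 2k − 2·loglik` over the `k` fitted parameters.

The Hassell family is fitted with `d` pinned at zero (attack rate
`bN0/(1+cN0)`), i.e. three free parameters — the classic type-III form; `d`
exists in the prediction API only as the algebraic device that reduces the
family to type II.

## Model-selection protocol

1. **Shape test (advisory).** Binomial GLM (logit link) of
   (eaten, not-eaten) on polynomial terms of density, fitted on a
   centered/scaled density for conditioning, cubic and quadratic terms
   backward-eliminated at α = 0.05, linear term always retained.
   Classification uses the raw-scale linear coefficient (delta-method SE):
   the logit slope at *low* density, negative-and-significant → hyperbolic
   (type-II candidate), positive-and-significant → sigmoidal, else
   indeterminate. Centered-scale linear terms are deliberately not used for
   classification: once curvature terms are retained they measure the slope
   at the mean density and can be near zero for strongly sigmoidal data.
   The test cannot distinguish type III from a generalized response, hence
   its advisory role.
2. **Flexible vs fixed exponent.** Fit the flexible-`q` model and the
   `q = 0` (Rogers type II) model; compare AIC. Differences smaller than a
   tie threshold (default 2.0) keep the model with fewer parameters.
3. **Generalized vs type III.** Only if the flexible model clearly wins,
   fit Hassell type III; the generalized response is retained only when its
   AIC also beats the type-III AIC (equal parameter counts make this a pure
   fit comparison).

A cell where no family converges with all non-`q` parameters significant at
α = 0.05 is reported as "no evidence of any functional response type",
with all diagnostics retained.

## Bootstrap confidence intervals

Nonparametric bootstrap: trials resampled with replacement within each
initial-density stratum (density is the design's fixed factor), each
resample refitted starting from the point estimates, 95% percentile
intervals from the converged resamples (BCa available as an option —
bias-correction from the resample distribution, acceleration from a
leave-one-out jackknife). The fraction of non-converged resamples is
reported and >50% flags the interval unreliable. At the study's size (30
trials per cell) percentile intervals measurably undercover (roughly 90%
observed for the attack rate in the package's own simulations — the
familiar small-sample bootstrap narrowing, of order sqrt((n−1)/n) per
stratum plus skewness effects); this is a property of the method at this
design size, not of the implementation, and is why the recovery tests
check coverage only up to Monte-Carlo error.

## Synthetic-data generator

The generator reproduces the study design exactly (densities, replicates,
treatments, contexts, T = 1) and draws consumption from a chosen generating
family under one of three noise models: `binomial` (matches the fitting
likelihood; the default, so that recovery tests isolate estimator
correctness), `exact_depletion` (a mechanistic renewal simulation — capture
waiting times exponential with rate `a_eff · N_remaining`, each capture
consuming `h` days of the remaining budget), and `beta_binomial` (an
overdispersion knob, off by default, because the original raw data are
unavailable and their variance model is unknown). Alternative-prey
consumption is drawn from treatment-level mean fractions (0.9/0.8/0.7 of
the 5/25/80 offered — the observed pattern of near-total consumption at low
offers declining at high offers) and is never used in fitting, exactly as
alternative prey enter the real analysis only as treatment labels.

What the generator does *not* emulate: predator-individual heterogeneity,
block (experimentation-day) effects, prey-switching dynamics between focal
and alternative prey, and any overdispersion beyond the optional
beta-binomial. Green recovery tests therefore demonstrate estimator
correctness under the assumed sampling model at the design's information
content, not robustness to every feature of real arenas.

A note on the mechanistic mode: the Rogers curve is the mean-field
(deterministic) limit of the renewal process, so the simulated mean carries
a finite-population offset from the prediction (≈0.4% at N0 = 80 with
type-II parameters of the parasitized-prey fit); tests assert agreement at
the 1% level rather than pretending the offset away.

## Problem sizes used by the checks

The recovery harness fits 500 simulated experiments (30 trials each);
bootstrap coverage uses 200 experiments at n_boot = 500; selection
consistency uses 200 seeds per generating family at 20 replicates per
density (with the 6-replicate design's rate recorded for context).
These sizes put Monte-Carlo error well below the tolerances being checked
while keeping a full run in the minutes range on one core.

## Known limitations

* Single-prey functional responses only; no multi-prey/prey-choice models.
* No random effects for blocks; trials are treated as exchangeable within a
  cell, as in the analysis the package mirrors.
* Wald/percentile inference is asymptotic/small-sample-biased as discussed
  above; profile-likelihood intervals are out of scope.
* The `q` exponent is fitted unconstrained; strongly negative `q` with very
  low densities is scientifically dubious and should be read as a
  diagnostic, not a mechanism.
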