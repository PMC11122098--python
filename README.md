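# frfit

Functional-response inference for predation-trial count data, built for
arena experiments with prey depletion — the setting of biological-control
studies in which a single predator (e.g. the big-eyed bug *Geocoris
punctipes*) is offered a fixed number of focal prey (whitefly nymphs,
parasitized or not) for a fixed exposure time, possibly alongside
alternative prey (aphids), and the number eaten is recorded.

## What it computes

A functional response relates prey density offered (N0) to prey eaten (Ne)
per predator per unit time. Because eaten prey are not replaced, the package
centers on depletion-corrected models:

* **Rogers type II** (random-predator equation):
  `Ne = N0 (1 − exp(a (h Ne − T)))`, solved in closed form via the
  Lambert-W function; `a` = attack rate (day⁻¹), `h` = handling time
  (days/prey), `T` = exposure (days).
* **Generalized (flexible-exponent) response**: the same equation with
  `a = b N0^q`; `q = 0` is type II, `q = 1` is type III, other values
  interpolate beyond both.
* **Hassell type III**: attack rate `(d + bN0)/(1 + cN0)` in the same
  depletion equation.
* **Holling type II** disc equation (no depletion), for reference.

On top of the curves: binomial maximum-likelihood fitting, Wald tests, a
Juliano-style polynomial-logistic shape test, AIC-based selection between
fixed- and flexible-exponent models (with a type-III comparison when the
flexible model wins), stratified nonparametric bootstrap confidence
intervals, maximum feeding rates `MFr = 1/(hT)`, and a synthetic-data
generator that reproduces the 5/10/25/50/80 × 6-replicate, four
alternative-prey-treatment, two-context study design. See
`docs/methods.md` for the full methodological account.

## Worked example

```python
from frfit import *

cfg = SyntheticConfig(
    family="rogers2",
    params=FRParameters(a=0.9797, h=0.0104, T=1.0),  # type-II truth
    seed=11,
)
ts = generate_experiment(cfg)          # 5 densities x 6 arena-days
sel = select_model(ts, seed=0)
print("chosen family:", sel.chosen)
print(sel.aic_table.to_string(index=False))

fit = sel.final
boot = bootstrap_ci(ts, "flexq", fix_q=0.0, n_boot=2000, seed=1, point=fit)
print(fit.to_frame().merge(boot.to_frame(), on="parameter").to_string(index=False))
print(f"maximum feeding rate: {fit.mfr:.1f} prey/day (reported: {round(fit.mfr)})")
```

prints

```
chosen family: rogers2
 family  k     loglik        aic  converged
  flexq  3 -67.624478 141.248955       True
rogers2  2 -67.704074 139.408147       True
 family parameter  estimate       se        z            p       mfr  ci_lower  ci_upper
rogers2         a  1.155757 0.129710 8.910322 5.088466e-19 78.635283  0.919824  1.461892
rogers2         h  0.012717 0.002539 5.008704 5.479766e-07 78.635283  0.007829  0.017131
maximum feeding rate: 78.6 prey/day (reported: 79)
```

Reading it: the flexible-exponent fit buys less than 2 AIC over the fixed
`q = 0` model, so the simpler Rogers type II is selected — correctly, since
the data were generated from it. The attack rate (1.16 ± 0.13 day⁻¹) and
handling time (0.0127 ± 0.0025 days/prey) bracket the generating values
(0.98, 0.0104) within their 95% bootstrap intervals; one 30-trial
experiment determines `h` only loosely, which is why the maximum feeding
rate (1/h = 79 prey/day here, 96 at the truth) is the quantity to watch.

The same pipeline is scriptable from the shell:

```sh
frfit simulate --seed 5 --out trials.csv --full-design
frfit run --input trials.csv --seed 2 --n-boot 500 --out reports/
```

which writes a consumption summary, shape-test coefficients, per-treatment
model selections with bootstrap intervals, and a JSON manifest that
reproduces the run.

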