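# sogmm

Growth mixture modeling under class-specific measurement noninvariance: a
simulation laboratory for comparing the common composite-score growth mixture
model (GMM) against the second-order growth mixture model (SOGMM).

## The problem

Applied growth mixture analyses usually average a scale's items into one
composite per occasion and fit latent trajectory classes to the composites.
That silently assumes the items work the same way in every latent class. When
they do not — when loadings or intercepts differ between classes (differential
item functioning, DIF) — the composite inherits the difference, and the
trajectory estimates absorb it. This package implements the full Monte Carlo
machinery for studying that failure mode and its remedy:

* a **synthetic-data module** generating two-class populations from a
  second-order growth mixture model (4 occasions × 6 items, linear growth,
  strict temporal invariance) across a 64-cell design: DIF location
  (loading/intercept) × size (0.20/0.40 loadings, 0.30/0.60 intercepts) ×
  factor-mean difference (none, or (1.4, 0.4) ≙ Mahalanobis separation 2.0) ×
  N ∈ {100, 200, 400, 1000} × mixing (50:50, 80:20);
* **maximum-likelihood estimation** of 1–3-class composite GMMs and SOGMMs by
  an ECM algorithm with closed-form conditional M-steps (marker-item
  identification, pooled within-class covariance structure, multi-start);
* **class enumeration** with AIC, BIC, sample-size-adjusted BIC, and the
  hierarchical BIC
  `HBIC = −2logL + (k0 + C − 1)·log n + Σ_c log(n·π_c)·k′_c`,
  which penalizes class-specific parameters with the class's effective sample
  size (HBIC = BIC at C = 1), plus the 5% minimum-class-proportion rule;
* **bias evaluation** (raw and relative bias of growth-factor means, their
  between-class differences, and DIF-size estimates, conditioned on correct
  enumeration), and
* a **closed-form oracle**: with mean item loading λ̄ and intercept ν̄ per
  class, a one-class composite fit recovers intercept Σ π_c(ν̄_c + λ̄_c κ_Ic)
  and slope Σ π_c λ̄_c κ_Sc, so the expected bias from ignoring DIF is
  available in closed form and is cross-validated against simulation.

It is written for methodologists and simulation authors in latent-variable
modeling; everything is importable Python with CSV/JSON artifacts.

## Worked example

```python
from sogmm import (Condition, ModelSpec, build_population, generate_dataset,
                   fit_mixture, select_model, predicted_one_class_bias)

cond = Condition("loading", "small", "none", 1000, "balanced")
pop = build_population(cond)               # two classes, DIF-only heterogeneity
print(predicted_one_class_bias(pop))       # (0.0067, -0.0333)

ds = generate_dataset(pop, cond.n_total, seed=7)
fits = {C: fit_mixture(ds, ModelSpec("composite_gmm", C), n_starts=8, seed=1)
        for C in (1, 2, 3)}
print(select_model(fits, ds.n).effective_C_by)
# {'aic': 1, 'bic': 1, 'sabic': 1, 'hbic': 1}
print(fits[1].estimates.classes[0].growth.kappa)
# [-0.0037  0.9863]  <- slope pulled below 1 by the ignored loading DIF
```

The oracle says ignoring a 0.20 loading DIF on 2 of 6 items biases the slope
mean by −2·0.20/6 · π₂ = −0.033; the fitted one-class slope on a single
replication lands near 0.986, and averaging over replications reproduces the
−0.033 (see `examples/` for runnable versions of each capability, and
`sogmm.pipeline.run_study` / the `sogmm-sim` CLI for configured sweeps over
the condition grid with CSV ledgers and rate/bias tables).

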