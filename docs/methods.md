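# Methods

`sogmm` is a Monte Carlo laboratory for studying what happens to growth mixture
modeling when the measurement model differs between latent classes. It
generates data from a two-class second-order growth mixture population with
class-specific item parameters, fits both the common composite-score growth
mixture model (GMM) and the second-order growth mixture model (SOGMM) by
maximum likelihood, enumerates classes with four information criteria, and
quantifies enumeration accuracy and parameter bias — together with a
closed-form oracle for the composite-score bias.

## Generating model

Each person belongs to latent class c with probability π_c. Within class, a
linear latent growth model drives four occasion factors

    η_t = ξ_I + t·ξ_S + ζ_t,   t = 0..3,
    ξ ~ N(κ_c, Φ),  ζ_t ~ N(0, ψ_t),

and each occasion factor is measured by six continuous items

    y_tj = ν_jc + λ_jc·η_t + ε_tj,   ε_tj ~ N(0, θ_j),

with strict invariance over time (λ, ν, θ shared across occasions) but
possible noninvariance across classes. The implied moments are

    μ_c = ν_c + Λ_c Γ κ_c,   Σ_c = Λ_c (Γ Φ Γ' + Ψ) Λ_c' + Θ,

with Γ = [1, t] the linear-growth design.

Reference-class parameters (shared by all conditions):

| parameter | value | notes |
|---|---|---|
| κ (intercept, slope means) | (0, 1) | latent metric |
| Φ | [[0.5, 0.089], [0.089, 0.1]] | factor correlation 0.4, variance ratio 5:1 |
| ψ_t | 0.3 (all occasions) | see below |
| λ | 1.00, 0.80, 0.95, 1.05, 0.95, 1.25 | mean 1.0, range 0.80–1.25 |
| ν | 0.00, −0.15, 0.25, 0.10, −0.10, −0.06 | range −0.15–0.25 |
| θ_j | 0.36 (all items) | |

The loading/intercept vectors and the disturbance variance are design choices
of this package: the published source of this design reports only the ranges,
the residual variance, and the item reliability span 0.59–0.91. The vectors
above have exactly the stated ranges, a mean loading of 1 (so composites are
on the latent metric up to the small intercept offset ν̄ = 0.0067), and with
ψ_t = 0.3 give reliabilities λ²V_t/(λ²V_t + θ) from 0.587 (λ = 0.80 at t = 0)
to 0.906 (λ = 1.25 at t = 3), matching the reported span. They also reproduce
the reported composite-bias values analytically (see the oracle below), which
is the strongest available constraint on the unprinted values.

## Condition grid

64 cells: DIF location (loading/intercept) × DIF size (small/large) × factor
mean difference (none/large) × N (100/200/400/1000) × mixing (50:50 / 80:20).
Noninvariance always sits on items 2 and 3 (item 1 stays invariant so it can
serve as the fitted marker): loading differences 0.20/0.40, intercept
differences 0.30/0.60. Under a factor-mean difference, class 2 has
κ = (1.4, 1.4) — Mahalanobis separation √(d'Φ⁻¹d) = 2.047 — and the
noninvariance is positively paired with growth status (the higher class
carries the higher loadings or intercepts). Without a mean difference class 2
carries the reduced loadings or the raised intercepts. Unbalanced mixing puts
0.8 on the class with higher means and/or measurement parameters.

Datasets are drawn through the latent structure (class label, growth factors,
disturbances, item errors) rather than from the marginal normal; the two are
equivalent, and the latent route documents the data-generating mechanism.
Seeds derive deterministically from (root seed, condition id, replication), so
any single replication can be regenerated in isolation.

## Fitted models and estimation

* **Composite GMM**: the four occasion means of the six items are the observed
  variables; per class, free growth means κ_c; pooled across classes, Φ and
  four occasion residual variances. k = 7 + (C−1) + 2C.
* **SOGMM**: all 24 items are observed; per class, κ_c and the ten non-marker
  measurement parameters (λ_2..λ_6, ν_2..ν_6); pooled, Φ, Ψ, Θ; marker item 1
  fixed at λ = 1, ν = 0 with temporal invariance imposed.
  k = 13 + (C−1) + 12C.

Pooling the within-class covariance structure mirrors the defaults of the
commercial SEM software this style of study is usually run in; a
`pooled_covariance=False` switch frees the full structure per class, with the
parameter counts adjusting. The marker-item identification puts the fitted and
generating metrics on the same scale, so bias is read off directly.

Both families are estimated by expectation-conditional-maximization. Treating
the growth factors and (for the SOGMM) the occasion disturbances as missing
data makes every conditional M-step closed form: posterior responsibilities
and latent conditional moments in the E-step; mixing proportions, growth
means, pooled covariance blocks, and per-(class, item) weighted regressions
for loadings/intercepts in the M-step. Closed-form CM steps were chosen over a
nested numerical M-step because they preserve the EM monotonicity guarantee
exactly, are an order of magnitude faster on the 24-indicator model, and have
no inner-optimizer failure modes. Monotonicity of the observed-data
log-likelihood is asserted per iteration in the test suite.

Numerical choices:

* Convergence: relative log-likelihood change < 1e-8, or an Aitken-accelerated
  projection of the remaining gain < 1e-4 — the projection is trusted only
  after several increment ratios agree (a transient saddle plateau shows
  fluctuating ratios and must not trigger it). The relative tolerance is
  deliberately tighter than the conventional 1e-6 because at the
  24-indicator likelihood magnitudes (|logL| ≈ 3·10⁴ at N = 1000) 1e-6
  relative leaves gaps comparable to information-criterion margins.
* Iteration cap 2000; a run ending at the cap with a final increment < 1e-3
  is treated as converged (it is within IC noise of its limit), otherwise it
  is flagged and excluded from model selection.
* Variance floor 1e-4 on all variances (eigenvalue clamp for Φ) to catch
  degenerate components.
* Multi-start: start 1 splits the single-class solution by symmetric ±1 SD
  growth-mean offsets; the remaining starts jitter growth means at cycling
  scales (0.5/1/2 SD) and (SOGMM) the measurement parameters, with equal
  mixing weights — perturbing the weights seeds degenerate tiny-class optima.
  With ≥ 4 starts the search is two-stage: a
  100-iteration burn-in for every start, then the top quarter run to full
  convergence. Defaults: 20 starts (composite), 10 (SOGMM). Ties between
  starts (< 1e-8) keep the lower start index for determinism.
* Empty components (responsibility mass < 1e-8) freeze their parameters and
  drop out of the pooled updates.

## Class enumeration

Candidate models with 1–3 classes are compared by AIC, BIC,
sample-size-adjusted BIC (penalty log((n+2)/24)·k), and hierarchical BIC,
which penalizes class-specific parameters with the class's effective sample
size: HBIC = −2logL + (k0 + C − 1)log(n) + Σ_c log(n π_c)·k′_c. HBIC equals
BIC at C = 1 and is smaller for C > 1; both identities are asserted. After the
argmin (ties toward fewer classes), any class holding under 5% of the
observations is discounted from the effective class count. Replications whose
selected fit did not converge are dropped from rate denominators, with drop
counts reported in the run manifest.

## Bias evaluation

Fitted classes are matched to generating classes by rank of the
intercept-factor mean (slope breaks ties); when the generating growth means
coincide — populations separated only by measurement noninvariance — the
match falls back to the measurement parameters on the DIF items, keeping the
sign convention of DIF estimates tied to the generating direction. Raw bias is
mean(estimate) − truth over the replications in which the conditioning
criterion (saBIC by default; summary tables in this literature rarely state one, so it is
configurable and always recorded) identified the correct class count;
relative bias divides by the truth and is undefined at truth 0. |relative
bias| > 0.05 is flagged as substantial. For no-mean-difference conditions the
one-class composite bias is taken against the latent truth (0, 1), which
deliberately includes the inherent composite offset (ν̄, and λ̄-scaling) — the
analytic module decomposes it.

## The closed-form bias oracle

Averaging the items at occasion t gives the composite trajectory of class c:
intercept a_c = ν̄_c + λ̄_c κ_Ic, slope b_c = λ̄_c κ_Sc. A one-class composite
fit to the pooled population recovers the π-weighted average line, so

    bias_I = Σ_c π_c a_c,   bias_S = Σ_c π_c b_c − 1.

Intercept DIF of size d on 2 of 6 items shifts ā by 2d/6 and biases only the
intercept mean (0.05/0.10 at the small/large sizes, balanced); loading DIF
scales λ̄ and biases only the slope mean (−0.033/−0.067); bias is linear in
the DIF size (superposition is asserted). For mean-difference populations the
same algebra predicts the relative bias of the recovered between-class
differences (e.g. 0.143 intercept, 0.333 slope at the large sizes); there it
is an approximation — a two-class fit reweights observations — and is accurate
when separation is large. Simulation agreement within 3 Monte Carlo standard
errors over all eight no-mean-difference cells is part of the acceptance
suite.

## What the generator does and does not emulate

It emulates the full factorial study design: class-specific measurement
parameters, the positive pairing of noninvariance with growth status, the
MD = 2 separation, and the balanced/unbalanced mixing. It does not emulate
features of real longitudinal item data such as error correlations over time,
categorical/ordinal items, missing data, temporal noninvariance, or non-linear
growth — all excluded by design. Passing tests therefore demonstrate correct
behavior under the stated population model, not robustness to those
real-data complications.

## Desk-scale profiles

The full study is 64 conditions × 500 replications × 2 families × 3 class
counts — hours of compute. The package's own test and reproduction profiles
are scaled down and state their sizes explicitly: bias cells use 100–150
replications at N = 1000 (Monte Carlo SE of a mean ≈ 0.002, well inside the
±0.01 comparisons); enumeration cells use 50–100 replications (SE of a rate
≤ 0.05); SOGMM cells use 50 replications with 3–4 starts. The `RunConfig`
defaults keep the full 500-replication, full-grid sweep available.

## Known limitations

* The per-item generating loadings/intercepts are a reconstruction constrained
  by the published ranges, reliability span, and bias values, not transcribed
  values; any set matching those constraints gives the same composite algebra.
* Enumeration rates that hinge on how aggressively the likelihood surface is
  searched (notably AIC's over-extraction rate on nearly-homogeneous data)
  reproduce the reported values only approximately: they are a property of
  the optimizer as much as of the criterion. BIC/saBIC/HBIC patterns are
  robust to search depth.
* The degree of DIF-size shrinkage in two-class SOGMM fits on measurement-only
  heterogeneity is likewise estimator-dependent. This implementation recovers
  the loading DIF nearly unbiasedly at moderate N and shows the shrinkage only
  at the weakest separations; for intercept DIF at small N the aligned class
  difference can even be inflated, a winner's-curse effect of matching classes
  on the very parameter that defines them. Reported shrinkage values from
  other software should not be expected to replicate in magnitude.
* The HBIC uses estimated mixing proportions in its penalty, so it is
  undefined for fits with an empty class (reported as missing, never silently
  substituted).
* Standard errors, likelihood-ratio-based enumeration (LMR, bootstrap LRT),
  and entropy-based diagnostics are out of scope.
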