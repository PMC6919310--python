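# Methods

## Model and assumptions

`visitjm` treats the times at which a longitudinal outcome is recorded as a
recurrent-event process in its own right. Each individual i carries a
binary treatment Z_i, a frailty u_i ~ N(0, σ²_u), an outcome random
intercept v_i ~ N(0, σ²_v), and an administrative censoring time
C_i ~ Unif(censor_lo, censor_hi). Everyone is observed at baseline (t = 0).
Subsequent visits occur on a gap-time (semi-Markov) clock with Weibull
proportional-hazards intensity

    r(t̃ | Z_i, u_i) = λ p t̃^(p−1) exp(β Z_i + u_i),

and the outcome recorded at visit time t_ij is

    y_ij = α₀ + α₁ Z_i + α₂ t_ij + γ u_i + v_i + ε_ij,   ε_ij ~ N(0, σ²_ε).

The frailty u enters both equations; γ scales its effect on the outcome and
is the "informativeness" parameter. Random effects are mutually
independent (diagonal covariance); correlated random effects, dropout
processes, flexible baseline hazards and time-varying treatment are out of
scope. The final, censored gap from the last visit to C_i contributes only
a survival factor.

## Likelihood and numerics (Model A)

The marginal likelihood integrates (u, v) out of the product of the
gap-time factors and the Gaussian outcome densities. Rather than a
two-dimensional quadrature, the package exploits the linearity of v:
conditional on u the outcomes of one individual are jointly Gaussian with
compound-symmetric covariance σ²_ε I + σ²_v J, so the v-integral has a
Woodbury closed form. What remains is a one-dimensional integral over u,
whose integrand is strictly log-concave; its mode is found by a damped
Newton iteration (vectorised across individuals) and the integral evaluated
by adaptive Gauss–Hermite quadrature centred and scaled at the mode
(default 9 nodes; 15–25 used in verification). This is exact in v, and the
whole construction is validated against brute-force two-dimensional Monte
Carlo integration of the raw integrand (10⁶ draws, agreement within Monte
Carlo error) in the test suite.

Optimisation is quasi-Newton (L-BFGS-B, finite-difference gradients) on an
unconstrained parameterisation: log λ, log p, log variances. Starting
values come from severing the model: a frailty-free Weibull recurrent-event
fit (with λ shrunk by exp(−σ²_u/2) to undo the frailty's marginal
inflation) plus a plain mixed-model fit, with γ started at 0 and σ²_u at
0.5. Standard errors on the natural scale follow by the delta method from
the inverse of the numerically differentiated observed information;
`converged` requires optimiser success and a positive-definite information
matrix. Failures are flagged, never raised, so simulation loops can count
them. Relative log-likelihood tolerance 1e-11, projected-gradient
tolerance 1e-6.

## Comparator estimators

* Models B/C/D are random-intercept LMMs fitted by full ML (never REML)
  through statsmodels MixedLM. Model B adds the individual's total number
  of measurements centred on the grand mean across individuals (an
  individual-level mean; a row-level mean would weight frequent attenders
  more). Model C adds the running measurement count *inclusive* of the
  current visit (1, 2, 3, …): the "informed presence" logic is that being
  measured now is itself informative. Both choices are degrees of freedom
  the published descriptions leave open; they are fixed here and tested.
  If the count covariate is degenerate (all individuals share one count)
  the adjusted model collapses to Model D with α₃ = 0.
* Model E estimates visit intensity with a gap-time Andersen–Gill Cox
  model (every non-baseline row is a spell from 0 to its gap; the terminal
  gap is a censored spell). The lifelines estimate is Newton-polished on
  the exact Breslow partial likelihood so that ties are handled by Breslow
  throughout and the score equation is solved to machine-level accuracy.
  A grouped (delete-one-individual) jackknife variance is available;
  simulation loops skip it because η's uncertainty enters no downstream
  quantity. Weights: raw = 1/exp(z'η̂) per measurement; recentred to mean
  1 by subtracting the mean and adding 1; shifted one position later
  within each individual (the weight attached to a visit is its
  predecessor's), baseline weight set to 1, each individual's trailing
  normalised weight discarded (the count is reported). The outcome model
  is weighted least squares of y on (1, Z, t) — identical to GEE with
  identity link and independence working correlation under probability
  weights — with a cluster-robust sandwich variance. Point estimates are
  invariant to rescaling all weights.

## Data-generating mechanisms

The simulator reproduces the study conditions the package is designed
around: n = 200 individuals, Z ~ Bernoulli(0.5), fixed effects
(α₀, α₁, α₂) = (0, 1, 0.2), variances (σ²_u, σ²_v, σ²_ε) = (1, 0.5, 1),
Weibull shape p = 1.05 with scale λ ∈ {0.10, 0.30, 1.00}, β = 1,
association γ ∈ {0, 1.5} (γ = 3 with λ = 0.05 in the planned-visits
scenario), and censoring Unif(5, 10) years. Weibull gaps are drawn by
inversion: t̃ = (−ln U / (λ e^{βZ+u}))^{1/p}. The Gamma mechanisms draw
gaps from Gamma(shape 2, scale exp(−ψβZ + ξ)) with ξ ~ N(0, 0.1) held
fixed within individual and ψ ∈ {0, 2}; the lagged variant multiplies the
scale by exp(ω y_prev) with ω = 0.2, so high recent outcomes lengthen the
next gap. In the planned-visits scenario, visits at 1, 2, … years (up to
C) are merged into the frailty-driven schedule without resetting its
gap-time clock — planned visits are exogenous interruptions — and gap
rows are recomputed from the merged time set; this yields the degenerate
observed-gap distribution (median and quartiles all 1.00). Outcomes at
planned visits follow the same outcome equation. Analytic marginal median
gap times (41-node Gauss–Hermite plus Brent root-finding in (1e-8, 1e3)
years, tolerance 1e-10) match the six scenario values 5.83/2.25,
2.05/0.79, 0.65/0.25 years and validate the simulator.

What the generator does *not* emulate: dropout or death, time-varying
treatment, measurement-error heteroscedasticity, within-day ties, or
cohort selection. Passing tests therefore demonstrate correctness of the
estimators under the stated mechanisms, not robustness to everything real
health-records data can do.

## Simulation engine and performance measures

Replicate seeds derive from a counter-based SeedSequence spawn key
(master_seed, scenario_index, replicate), so every cell is independently
reproducible and all methods within a replicate see the same data.
Summaries per (scenario, method, estimand): bias (mean and median based),
empirical SE, mean model SE, coverage of nominal 95% Wald intervals
(±1.96·SE on the natural scale, variance parameters included), MSE, and
Monte Carlo standard errors: MCSE(bias) = empSE/√K, MCSE(empSE) =
empSE/√(2(K−1)), MCSE(coverage) = √(c(1−c)/K), MCSE(mse) =
sd((θ̂−θ)²)/√K. Non-convergent replicates are excluded cell-wise and the
convergence rate reported. The identity mse = bias² + empSE²·(K−1)/K is
asserted to 1e-10.

## Problem sizes used by the test suite

The full design (K = 1,000 replicates, five methods, ten scenarios) is
available through the shipped `study_paper.yaml` preset. The package's own
verification runs at smaller, fixed sizes chosen to exercise every claim:
simulator descriptives at K = 200 datasets per scenario (the acceptance
script uses K = 1,000 for its simulated targets), the directional bias
study at K = 100 (γ = 0) and K = 200 (γ = 1.5), parameter recovery on one
n = 2,000 dataset, and the planned-visits association study at K = 12.
At K = 100–200 a z-test on bias resolves effects larger than roughly
3·empSE/√K ≈ 0.06–0.08 outcome units for the treatment effect; smaller
real biases (the plain mixed model's treatment-effect bias is about
−0.04 under γ = 1.5, λ = 0.30) are detectable only at the full K = 1,000.

## Known limitations

* **Weak identification under planned visits.** With yearly planned
  visits dominating a sparse frailty-driven schedule (γ = 3, λ = 0.05),
  the observed gaps are nearly deterministic and carry almost no
  information about u, so γ and σ²_u are separately unidentified: the
  likelihood rewards trading σ²_u down for |γ| up while γ²σ²_u (the
  outcome-side heterogeneity) and the near-zero visit-side frailty stay
  fixed. The maximiser found here has γ̂ ≈ +13 with σ̂²_u ≈ 0.05 — note
  γ̂·σ̂_u ≈ 3, the generating γ·σ_u — and a markedly higher likelihood
  than solutions with γ̂ near zero; software that stops at a local mode
  near its starting values instead reports a small shrunken (even
  sign-flipped) γ̂. Either way the association parameter is not
  recoverable in this design; conclusions about γ should not be drawn
  from schedules dominated by planned visits. Convergence flags drop in
  this scenario because σ̂²_v hits its boundary.
* ML (not REML) variance estimates are slightly negatively biased at
  n = 200; this is inherent to the estimand definition, not corrected.
* The joint model assumes the visit process is conditionally
  non-informative given u (observation at random); nothing in the fit can
  detect dependence on unrecorded current outcomes.
* Variance-parameter standard errors are reported for the joint model
  (delta method) but not for the MixedLM comparators, where coverage is
  assessed for fixed effects only.
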