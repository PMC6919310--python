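# visitjm

Joint models and comparator estimators for longitudinal data whose
measurement times come from an **informative visiting process**, with a full
Monte Carlo simulation engine for comparing them.

## The problem

In electronic health records, a biomarker is recorded only when a patient
visits — and sicker patients visit more often and carry worse values. The
times at which the outcome is observed are then correlated with the outcome
itself, and an ordinary mixed model fitted to the recorded values can be
biased. `visitjm` implements, and lets you stress-test against each other:

* **Model A — the joint model.** A Weibull proportional-hazards model for
  the gap time t̃ between consecutive visits,

      r(t̃ | Z, u) = λ p t̃^(p−1) exp(βZ + u),

  coupled with a Gaussian linear model for the outcome recorded at each
  visit,

      y_ij = α₀ + α₁ Z_i + α₂ t_ij + γ u_i + v_i + ε_ij,

  where u_i ~ N(0, σ²_u) is a frailty shared between the two submodels,
  v_i ~ N(0, σ²_v) an outcome random intercept, and ε_ij ~ N(0, σ²_ε).
  The association parameter γ measures how informative the visiting process
  is (γ = 0 ⇒ not informative). Estimation is by maximum marginal
  likelihood: v is integrated out in closed form, u by adaptive
  Gauss–Hermite quadrature.
* **Models B/C/D** — random-intercept linear mixed models (ML, not REML)
  adjusting for the centred total visit count, the cumulative visit count,
  or nothing.
* **Model E** — inverse intensity of visiting weighting (IIVW): an
  Andersen–Gill gap-time Cox model for the visit intensity, normalised and
  shifted inverse-intensity weights, and a weighted marginal outcome model
  with cluster-robust variance.

The `simulate` module generates data under joint-model and Gamma gap-time
mechanisms (with or without treatment and lagged-outcome dependence, with
or without planned yearly visits); `performance` runs replicate × scenario
× method grids and reports bias, empirical SE, coverage and MSE with Monte
Carlo standard errors; `analytic` provides quadrature reference quantities
such as the marginal median gap time.

## Worked example

```python
from visitjm import ScenarioConfig, simulate_scenario, fit_joint_model, fit_lmm

cfg = ScenarioConfig(dgm_kind="joint", lam=0.30, gamma_assoc=1.5, seed=42)
data = simulate_scenario(cfg)          # 200 individuals, informative visits
fit = fit_joint_model(data)
print({k: float(round(v, 3)) for k, v in fit.estimates.items()})
print("plain mixed model alpha1:", round(fit_lmm(data).estimates["alpha1"], 3))
```

prints

```
{'lambda': 0.329, 'p': 1.049, 'beta': 0.902, 'alpha0': 0.121, 'alpha1': 0.797,
 'alpha2': 0.2, 'gamma': 1.562, 'sigma2_u': 0.996, 'sigma2_v': 0.416,
 'sigma2_eps': 1.018}
plain mixed model alpha1: 0.76
```

The joint model recovers the generating values (λ = 0.30, γ = 1.5,
α₁ = 1 within its standard error of 0.25), while the plain mixed model,
which ignores why this patient was measured 9 times and that one twice,
underestimates the treatment effect. On this single draw both point
estimates of α₁ sit below 1; over many replicates the joint model is
unbiased and the plain model is systematically low (see
`visitjm study --config src/visitjm/presets/study_desk.yaml`).

The same machinery is available from the shell:

```bash
visitjm simulate --config jm_g150_l030 --seed 42 --out data.csv
visitjm fit --data data.csv --method A --out fit.json
visitjm weights --data data.csv --out weighted.csv
visitjm medians --lam 0.10        # -> 5.83 (Z=0) and 2.25 (Z=1) years
visitjm study --config src/visitjm/presets/study_desk.yaml
```

Scenario presets for every data-generating mechanism of the simulation
study ship in `src/visitjm/presets/`.

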