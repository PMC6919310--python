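"""Likelihood and fitting checks for the shared-frailty joint model.

The oracles here are deliberately independent of the implementation: plain
Monte Carlo integration over both random effects, one-dimensional scipy
quadrature, and hand-written Weibull/Gaussian log-likelihoods.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from visitjm import FitResult, ScenarioConfig, fit_joint_model, joint_loglik, simulate_scenario
from visitjm.joint_model import JointModelParams, NumericalError

from conftest import make_panel

PARAMS = JointModelParams(
    lam=0.3, p=1.05, beta=1.0, alpha0=0.0, alpha1=1.0, alpha2=0.2,
    gamma_assoc=1.5, sigma2_u=1.0, sigma2_v=0.5, sigma2_eps=1.0,
)


def _toy_three_individuals():
    rows = [
        # id, j, t, gap, d, y, Z, C
        (0, 0, 0.0, 0.0, 1, 0.4, 0, 6.0),
        (0, 1, 1.2, 1.2, 1, 1.1, 0, 6.0),
        (0, 2, 2.0, 0.8, 1, -0.3, 0, 6.0),
        (0, 3, 6.0, 4.0, 0, np.nan, 0, 6.0),
        (1, 0, 0.0, 0.0, 1, 2.2, 1, 5.5),
        (1, 1, 0.7, 0.7, 1, 1.9, 1, 5.5),
        (1, 2, 5.5, 4.8, 0, np.nan, 1, 5.5),
        (2, 0, 0.0, 0.0, 1, -0.9, 0, 7.0),
        (2, 1, 3.1, 3.1, 1, 0.5, 0, 7.0),
        (2, 2, 4.4, 1.3, 1, 1.5, 0, 7.0),
        (2, 3, 7.0, 2.6, 0, np.nan, 0, 7.0),
    ]
    return make_panel(rows)


def _mc_loglik_per_individual(data, params, n_draws, seed):
    """Brute-force Monte Carlo integration over (u, v); returns (log L_i, se_log)."""
    rng = np.random.default_rng(seed)
    out = []
    for _, g in data.data.groupby("id"):
        u = rng.normal(0.0, np.sqrt(params.sigma2_u), n_draws)
        v = rng.normal(0.0, np.sqrt(params.sigma2_v), n_draws)
        Z = g["Z"].iloc[0]
        loga = np.zeros(n_draws)
        for _, row in g[g["j"] > 0].iterrows():
            expo = params.lam * row["gap"] ** params.p * np.exp(params.beta * Z + u)
            if row["d"] == 1:
                loga += (
                    np.log(params.lam * params.p)
                    + (params.p - 1.0) * np.log(row["gap"])
                    + params.beta * Z + u
                )
            loga -= expo
        for _, row in g[g["d"] == 1].iterrows():
            m = (
                params.alpha0 + params.alpha1 * Z + params.alpha2 * row["t"]
                + params.gamma_assoc * u + v
            )
            loga += stats.norm.logpdf(row["y"], m, np.sqrt(params.sigma2_eps))
        vals = np.exp(loga)
        est = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(n_draws)
        out.append((np.log(est), se / est))
    return out


def test_loglik_matches_monte_carlo_integration():
    """Quadrature equals brute-force 2-D Monte Carlo within 3 MC SEs."""
    data = _toy_three_individuals()
    mc = _mc_loglik_per_individual(data, PARAMS, n_draws=1_000_000, seed=1234)
    for (i, g), (log_mc, se_log) in zip(data.data.groupby("id"), mc):
        from visitjm.simulate import PanelDataset

        sub = PanelDataset(data=g.reset_index(drop=True))
        ll = joint_loglik(PARAMS, sub, n_quad=25)
        assert abs(ll - log_mc) < 3.0 * se_log


def _weibull_frailty_loglik(data, params):
    """1-D scipy quadrature oracle for the visit-process factor (gamma = 0)."""
    total = 0.0
    for _, g in data.data.groupby("id"):
        Z = g["Z"].iloc[0]
        gaps = g.loc[g["j"] > 0, "gap"].to_numpy()
        d = g.loc[g["j"] > 0, "d"].to_numpy()

        def integrand(u):
            ll = np.sum(
                d * (np.log(params.lam * params.p) + (params.p - 1) * np.log(gaps)
                     + params.beta * Z + u)
                - params.lam * gaps**params.p * np.exp(params.beta * Z + u)
            )
            return np.exp(ll) * stats.norm.pdf(u, 0.0, np.sqrt(params.sigma2_u))

        val, _ = integrate.quad(integrand, -10, 10, limit=200)
        total += np.log(val)
    return total


def _lmm_loglik(data, params):
    """Exact Gaussian random-intercept log-likelihood via scipy MVN."""
    total = 0.0
    for _, g in data.data.groupby("id"):
        obs = g[g["d"] == 1]
        y = obs["y"].to_numpy()
        m = params.alpha0 + params.alpha1 * obs["Z"] + params.alpha2 * obs["t"]
        cov = params.sigma2_v * np.ones((len(y), len(y))) + params.sigma2_eps * np.eye(len(y))
        total += stats.multivariate_normal.logpdf(y, m.to_numpy(), cov)
    return total


def test_zero_association_factorises_the_likelihood():
    """gamma = 0 severs the link: joint loglik = frailty-Weibull + Gaussian LMM."""
    data = _toy_three_individuals()
    severed = JointModelParams(0.3, 1.05, 1.0, 0.0, 1.0, 0.2, 0.0, 1.0, 0.5, 1.0)
    expected = _weibull_frailty_loglik(data, severed) + _lmm_loglik(data, severed)
    assert joint_loglik(severed, data, n_quad=30) == pytest.approx(expected, abs=1e-6)


def test_degenerate_frailty_gives_plain_weibull_plus_lmm():
    """sigma2_u = 0 collapses the integral to u = 0 (no frailty at all)."""
    data = _toy_three_individuals()
    p0 = JointModelParams(0.3, 1.05, 1.0, 0.0, 1.0, 0.2, 0.0, 0.0, 0.5, 1.0)
    expected = _weibull_frailty_loglik_at_u0(data, p0) + _lmm_loglik(data, p0)
    assert joint_loglik(p0, data, n_quad=9) == pytest.approx(expected, abs=1e-8)


def _weibull_frailty_loglik_at_u0(data, params):
    total = 0.0
    for _, g in data.data.groupby("id"):
        Z = g["Z"].iloc[0]
        gaps = g.loc[g["j"] > 0, "gap"].to_numpy()
        d = g.loc[g["j"] > 0, "d"].to_numpy()
        total += np.sum(
            d * (np.log(params.lam * params.p) + (params.p - 1) * np.log(gaps)
                 + params.beta * Z)
            - params.lam * gaps**params.p * np.exp(params.beta * Z)
        )
    return total


def test_single_censored_gap_reduces_to_survival_integral():
    """One censored gap, no outcomes: the v-integral is 1 and only the
    survival factor remains."""
    rows = [(0, 0, 0.0, 2.5, 0, np.nan, 1, 2.5)]
    data = make_panel(rows)
    data.data.loc[0, "j"] = 1  # a bare censored spell, no baseline measurement

    def integrand(u):
        return (
            np.exp(-PARAMS.lam * 2.5**PARAMS.p * np.exp(PARAMS.beta * 1 + u))
            * stats.norm.pdf(u, 0.0, 1.0)
        )

    expected, _ = integrate.quad(integrand, -12, 12, limit=200)
    assert joint_loglik(PARAMS, data, n_quad=30) == pytest.approx(np.log(expected), abs=1e-8)


def test_loglik_invariant_to_individual_and_row_permutation(small_data):
    base = joint_loglik(PARAMS, small_data, n_quad=9)
    shuffled = small_data.data.sample(frac=1.0, random_state=7)
    from visitjm.simulate import PanelDataset

    assert joint_loglik(PARAMS, PanelDataset(data=shuffled), n_quad=9) == pytest.approx(
        base, abs=1e-9
    )


def test_quadrature_node_count_converged(joint_data):
    ll15 = joint_loglik(PARAMS, joint_data, n_quad=15)
    ll25 = joint_loglik(PARAMS, joint_data, n_quad=25)
    assert abs(ll15 - ll25) < 1e-4


def test_loglik_peaks_near_generating_parameters():
    """At n = 500 the generating values beat any +0.5 single-coordinate bump."""
    cfg = ScenarioConfig(dgm_kind="joint", lam=0.3, gamma_assoc=1.5,
                         n_individuals=500, seed=77)
    data = simulate_scenario(cfg)
    base = joint_loglik(PARAMS, data, n_quad=9)
    x0 = PARAMS.as_array()
    for k in range(len(x0)):
        x = x0.copy()
        x[k] += 0.5
        assert joint_loglik(JointModelParams.from_array(x), data, n_quad=9) < base


def test_time_rescaling_equivariance(small_data):
    """Scaling time by c maps (lam, alpha2) -> (lam c^-p, alpha2/c) and shifts
    the loglik by -(number of events) * log c (the Jacobian)."""
    c = 2.0
    from visitjm.simulate import PanelDataset

    df = small_data.data.copy()
    df[["t", "gap", "C"]] *= c
    scaled = PanelDataset(data=df)
    mapped = JointModelParams(
        PARAMS.lam * c**-PARAMS.p, PARAMS.p, PARAMS.beta, PARAMS.alpha0,
        PARAMS.alpha1, PARAMS.alpha2 / c, PARAMS.gamma_assoc,
        PARAMS.sigma2_u, PARAMS.sigma2_v, PARAMS.sigma2_eps,
    )
    n_events = int(((small_data.data["j"] > 0) & (small_data.data["d"] == 1)).sum())
    ll = joint_loglik(PARAMS, small_data, n_quad=15)
    ll_scaled = joint_loglik(mapped, scaled, n_quad=15)
    assert ll_scaled == pytest.approx(ll - n_events * np.log(c), abs=1e-6)


def test_fit_recovers_generating_parameters(joint_data):
    """Point estimates on one n = 200 dataset stay within ~4 SEs of truth."""
    fit = fit_joint_model(joint_data)
    assert fit.converged
    truth = dict(zip(fit.names, PARAMS.as_array()))
    for name, true_val in truth.items():
        z = abs(fit.estimates[name] - true_val) / fit.se[name]
        assert z < 4.0, f"{name}: z = {z:.2f}"
    # vcov is symmetric PSD when converged
    assert np.allclose(fit.vcov, fit.vcov.T)
    assert np.all(np.linalg.eigvalsh(fit.vcov) > -1e-10)


def test_invalid_inputs_rejected(small_data):
    with pytest.raises(ValueError):
        joint_loglik(PARAMS, small_data, n_quad=2)
    with pytest.raises(ValueError):
        JointModelParams(-0.1, 1.0, 0, 0, 0, 0, 0, 1, 1, 1)
    with pytest.raises(ValueError):
        JointModelParams(0.1, 1.0, 0, 0, 0, 0, 0, -1, 1, 1)


def test_numerical_failure_is_signalled(small_data):
    """Non-finite parameters raise unless the optimiser-facing mode is on."""
    bad = JointModelParams(0.3, 1.05, 1.0, np.nan, 1, 0.2, 1.5, 1.0, 0.5, 1.0)
    with pytest.raises(NumericalError):
        joint_loglik(bad, small_data, n_quad=9)
    assert joint_loglik(bad, small_data, n_quad=9, on_fail="-inf") == -np.inf


def test_fit_result_json_round_trip(tmp_path, small_data):
    fit = fit_joint_model(small_data)
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = FitResult.from_json(path)
    assert back.method == fit.method
    assert back.estimates == pytest.approx(fit.estimates)
    assert back.se == pytest.approx(fit.se)
    assert back.converged == fit.converged
    np.testing.assert_allclose(back.vcov, fit.vcov)
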