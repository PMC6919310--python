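"""Maximum-likelihood estimation of the shared-frailty joint model (Model A).

The model couples a Weibull gap-time intensity for the visiting process,

    r(t | Z_i, u_i) = lam * p * t**(p-1) * exp(beta*Z_i + u_i),

with a Gaussian longitudinal submodel for the outcome recorded at each
visit,

    y_ij = alpha0 + alpha1*Z_i + alpha2*t_ij + gamma*u_i + v_i + eps_ij,

where u_i ~ N(0, sigma2_u) is shared between the two processes, v_i ~
N(0, sigma2_v) is an outcome-specific random intercept, and eps_ij ~
N(0, sigma2_eps).  The association parameter gamma measures how strongly
the visiting process is informative; gamma = 0 severs the link.

The marginal likelihood integrates both random effects out.  Because v_i
enters the outcome equation linearly, its integral is available in closed
form (conditional on u the outcomes are jointly Gaussian with a
compound-symmetric covariance), leaving a one-dimensional integral over u
which is evaluated by adaptive Gauss-Hermite quadrature centred on the
per-individual posterior mode of u.  The integrand is strictly log-concave
in u, so the mode is found by a globally convergent Newton iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, roots_hermite

from .results import FitResult
from .simulate import PanelDataset

__all__ = ["JointModelParams", "joint_loglik", "fit_joint_model", "NumericalError"]

PARAM_NAMES = [
    "lambda",
    "p",
    "beta",
    "alpha0",
    "alpha1",
    "alpha2",
    "gamma",
    "sigma2_u",
    "sigma2_v",
    "sigma2_eps",
]


class NumericalError(RuntimeError):
    """Raised when the quadrature produces non-finite values."""


@dataclass(frozen=True)
class JointModelParams:
    lam: float
    p: float
    beta: float
    alpha0: float
    alpha1: float
    alpha2: float
    gamma_assoc: float
    sigma2_u: float
    sigma2_v: float
    sigma2_eps: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.p > 0):
            raise ValueError("lam and p must be positive")
        if min(self.sigma2_u, self.sigma2_v) < 0 or self.sigma2_eps <= 0:
            raise ValueError("variances must be non-negative and sigma2_eps positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.lam,
                self.p,
                self.beta,
                self.alpha0,
                self.alpha1,
                self.alpha2,
                self.gamma_assoc,
                self.sigma2_u,
                self.sigma2_v,
                self.sigma2_eps,
            ]
        )

    @classmethod
    def from_array(cls, x) -> "JointModelParams":
        return cls(*[float(v) for v in x])


@dataclass
class _Sufficient:
    """Per-individual sufficient statistics, shared by every likelihood call."""

    Z: np.ndarray  # (G,)
    D: np.ndarray  # events (observed non-baseline visits) per individual
    slg: np.ndarray  # sum of log gap over event rows
    gaps: np.ndarray  # pooled gap times, all non-baseline rows
    gap_groups: np.ndarray  # reduceat boundaries into `gaps`
    n_obs: np.ndarray  # outcomes per individual
    y: np.ndarray  # pooled outcomes
    t: np.ndarray  # pooled observation times for outcome rows
    Zy: np.ndarray  # treatment per outcome row
    y_groups: np.ndarray


def _sufficient(data: PanelDataset) -> _Sufficient:
    df = data.data
    ids = df["id"].to_numpy()
    order = np.argsort(ids, kind="stable")
    df = df.iloc[order]
    ids = df["id"].to_numpy()
    _, first = np.unique(ids, return_index=True)

    gap_rows = df[df["j"] > 0]
    obs_rows = df[df["d"] == 1]
    gids = gap_rows["id"].to_numpy()
    oids = obs_rows["id"].to_numpy()
    uniq = np.unique(ids)

    Z = df["Z"].to_numpy()[first].astype(float)
    ev = gap_rows[gap_rows["d"] == 1]
    D = np.bincount(np.searchsorted(uniq, ev["id"].to_numpy()), minlength=len(uniq)).astype(float)
    slg = np.zeros(len(uniq))
    np.add.at(slg, np.searchsorted(uniq, ev["id"].to_numpy()), np.log(ev["gap"].to_numpy()))

    gap_idx = np.searchsorted(uniq, gids)
    gap_groups = np.searchsorted(gap_idx, np.arange(len(uniq)))
    y_idx = np.searchsorted(uniq, oids)
    y_groups = np.searchsorted(y_idx, np.arange(len(uniq)))
    n_obs = np.bincount(y_idx, minlength=len(uniq)).astype(float)

    return _Sufficient(
        Z=Z,
        D=D,
        slg=slg,
        gaps=gap_rows["gap"].to_numpy(dtype=float),
        gap_groups=gap_groups,
        n_obs=n_obs,
        y=obs_rows["y"].to_numpy(dtype=float),
        t=obs_rows["t"].to_numpy(dtype=float),
        Zy=obs_rows["Z"].to_numpy(dtype=float),
        y_groups=y_groups,
    )


def _percluster_loglik(params: JointModelParams, suf: _Sufficient, n_quad: int) -> np.ndarray:
    """Log marginal likelihood contribution of each individual."""
    lam, p = params.lam, params.p
    g, s2u, s2v, s2e = params.gamma_assoc, params.sigma2_u, params.sigma2_v, params.sigma2_eps

    # visit-process statistics
    Sp = np.add.reduceat(suf.gaps**p, suf.gap_groups)
    A = lam * np.exp(params.beta * suf.Z) * Sp

    # outcome statistics with v integrated out analytically:
    # residuals at u = 0, e = y - (a0 + a1 Z + a2 t)
    e = suf.y - (params.alpha0 + params.alpha1 * suf.Zy + params.alpha2 * suf.t)
    Se = np.add.reduceat(e, suf.y_groups) if len(e) else np.zeros_like(suf.n_obs)
    See = np.add.reduceat(e**2, suf.y_groups) if len(e) else np.zeros_like(suf.n_obs)
    Se[suf.n_obs == 0] = 0.0
    See[suf.n_obs == 0] = 0.0
    n = suf.n_obs

    denom = s2e + n * s2v
    c = s2v / (s2e * denom)  # Woodbury correction factor
    gauss_const = -0.5 * (n * np.log(2 * np.pi * s2e) + np.log1p(n * s2v / s2e))

    # g(u) = K0 + K1*u + K2*u^2 - A*exp(u): strictly concave for s2u > 0
    K0 = (
        suf.D * (np.log(lam * p) + params.beta * suf.Z)
        + (p - 1.0) * suf.slg
        + gauss_const
        - 0.5 * (See / s2e - c * Se**2)
    )
    K1 = suf.D + g * Se / s2e - c * Se * n * g
    K2 = -0.5 * (n * g**2 / s2e - c * n**2 * g**2)

    if s2u == 0.0:
        return K0 + K2 * 0.0 - A  # integrand collapses to u = 0 (K1*0, K2*0)

    K0 = K0 - 0.5 * np.log(2 * np.pi * s2u)
    K2 = K2 - 0.5 / s2u

    # Newton iteration for the per-individual mode of g
    u = np.zeros_like(A)
    for _ in range(200):
        Aeu = A * np.exp(np.clip(u, -700.0, 700.0))
        grad = K1 + 2.0 * K2 * u - Aeu
        hess = 2.0 * K2 - Aeu
        step = np.clip(grad / hess, -4.0, 4.0)  # damp: exp term can overshoot
        u -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    sd = 1.0 / np.sqrt(-(2.0 * K2 - A * np.exp(u)))

    x, w = roots_hermite(n_quad)
    U = u[:, None] + np.sqrt(2.0) * sd[:, None] * x[None, :]
    gU = K0[:, None] + K1[:, None] * U + K2[:, None] * U**2 - A[:, None] * np.exp(U)
    logint = logsumexp(gU + x[None, :] ** 2 + np.log(w)[None, :], axis=1)
    return logint + 0.5 * np.log(2.0) + np.log(sd)


def joint_loglik(
    params: JointModelParams,
    data: PanelDataset | _Sufficient,
    n_quad: int = 15,
    on_fail: str = "raise",
) -> float:
    """Marginal log-likelihood of the joint model, random effects integrated out.

    ``on_fail='raise'`` signals numerical failure with :class:`NumericalError`;
    ``on_fail='-inf'`` returns ``-inf`` instead (optimiser-facing mode).
    """
    if n_quad < 3:
        raise ValueError("n_quad must be >= 3")
    suf = data if isinstance(data, _Sufficient) else _sufficient(data)
    with np.errstate(over="ignore", invalid="ignore"):
        contrib = _percluster_loglik(params, suf, n_quad)
    total = float(np.sum(contrib))
    if not np.isfinite(total):
        if on_fail == "-inf":
            return -np.inf
        raise NumericalError("quadrature produced a non-finite log-likelihood")
    return total


# -- fitting ---------------------------------------------------------------

def _transform(params: JointModelParams) -> np.ndarray:
    x = params.as_array()
    out = x.copy()
    for k in (0, 1, 7, 8, 9):  # lam, p, variances on log scale
        out[k] = np.log(x[k])
    return out


def _untransform(x: np.ndarray) -> JointModelParams:
    y = np.asarray(x, dtype=float).copy()
    for k in (0, 1, 7, 8, 9):
        y[k] = np.exp(y[k])
    return JointModelParams.from_array(y)


def _weibull_start(suf: _Sufficient) -> tuple[float, float, float]:
    """No-frailty Weibull recurrent-event fit for starting values."""

    def nll(x):
        lam, p, beta = np.exp(x[0]), np.exp(x[1]), x[2]
        Sp = np.add.reduceat(suf.gaps**p, suf.gap_groups)
        ll = np.sum(
            suf.D * (np.log(lam * p) + beta * suf.Z)
            + (p - 1.0) * suf.slg
            - lam * np.exp(beta * suf.Z) * Sp
        )
        return -ll

    res = minimize(nll, np.array([np.log(0.3), 0.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    return float(np.exp(res.x[0])), float(np.exp(res.x[1])), float(res.x[2])


def _lmm_start(data: PanelDataset) -> tuple[float, float, float, float, float]:
    from .lmm_comparators import LmmSpec, fit_lmm

    fit = fit_lmm(data, LmmSpec(adjustment="none"))
    est = fit.estimates
    return est["alpha0"], est["alpha1"], est["alpha2"], max(est["sigma2_v"], 1e-3), max(
        est["sigma2_eps"], 1e-3
    )


def fit_joint_model(
    data: PanelDataset,
    n_quad: int = 9,
    start: JointModelParams | None = None,
    sigma2_u_start: float = 0.5,
    maxiter: int = 500,
) -> FitResult:
    """Fit Model A by maximum marginal likelihood.

    Optimisation is quasi-Newton (L-BFGS-B with finite-difference gradients)
    on an unconstrained parameterisation (log scale for lam, p and the
    variances); standard errors on the natural scale follow by the delta
    method from the inverse of the numerically differentiated observed
    information.  Failures are reported via ``converged=False``, never
    raised, so simulation loops can record them.
    """
    suf = _sufficient(data)
    try:
        if start is None:
            wlam, wp, wbeta = _weibull_start(suf)
            a0, a1, a2, s2v, s2e = _lmm_start(data)
            # the no-frailty scale absorbs E[exp(u)]; shrink it accordingly
            start = JointModelParams(
                lam=wlam * np.exp(-sigma2_u_start / 2.0),
                p=wp,
                beta=wbeta,
                alpha0=a0,
                alpha1=a1,
                alpha2=a2,
                gamma_assoc=0.0,
                sigma2_u=sigma2_u_start,
                sigma2_v=s2v,
                sigma2_eps=s2e,
            )

        def nll(x):
            return -joint_loglik(_untransform(x), suf, n_quad, on_fail="-inf")

        res = minimize(
            nll,
            _transform(start),
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
        params = _untransform(res.x)
        loglik = -res.fun

        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(res.x, nll)
        ev = np.linalg.eigvalsh(H)
        info_pd = bool(np.all(ev > 0))
        if info_pd:
            vcov_t = np.linalg.inv(H)
            jac = np.ones(10)
            nat = params.as_array()
            for k in (0, 1, 7, 8, 9):
                jac[k] = nat[k]
            vcov = vcov_t * np.outer(jac, jac)
            se = np.sqrt(np.clip(np.diag(vcov), 0.0, np.inf))
        else:
            vcov = np.full((10, 10), np.nan)
            se = np.full(10, np.nan)

        converged = bool(res.success) and info_pd and np.isfinite(loglik)
        est = dict(zip(PARAM_NAMES, params.as_array()))
        return FitResult(
            method="A",
            estimates=est,
            se=dict(zip(PARAM_NAMES, se)),
            vcov=vcov,
            loglik=loglik,
            converged=converged,
            n_quad=n_quad,
            iterations=int(res.nit),
        )
    except Exception as exc:  # contract: optimisation failure is data, not an error
        warnings.warn(f"joint model fit failed: {exc}")
        nanp = {k: np.nan for k in PARAM_NAMES}
        return FitResult(
            method="A",
            estimates=dict(nanp),
            se=dict(nanp),
            vcov=None,
            loglik=np.nan,
            converged=False,
            n_quad=n_quad,
        )
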