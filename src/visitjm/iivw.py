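"""Inverse-intensity-of-visiting weighting (Model E).

A two-stage marginal estimator for longitudinal data with an informative
visiting process:

1. the visit intensity is modelled on the gap-time scale with an
   Andersen-Gill recurrent-events model ``r(t) = r0(t) exp(z'eta)``; each
   gap is a spell from 0 to the gap length, censored for the terminal gap.
   ``eta`` is estimated by Cox partial likelihood (Breslow tie handling)
   with a grouped, delete-one-individual jackknife variance;
2. each recorded measurement is weighted by the inverse of its estimated
   relative intensity ``exp(z'eta)``, the weights are recentred to mean 1,
   shifted one position later within each individual (the weight attached
   to a visit is the one computed for its predecessor), and the baseline
   measurement receives weight 1.  A marginal model
   ``E(y) = alpha0 + alpha1*Z + alpha2*t`` is then fit by weighted
   estimating equations with an independence working structure and a
   cluster-robust sandwich variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .results import FitResult
from .simulate import PanelDataset

__all__ = [
    "VisitIntensityFit",
    "VisitWeights",
    "fit_visit_intensity",
    "compute_weights",
    "fit_weighted_marginal",
    "fit_iivw",
]


@dataclass
class VisitIntensityFit:
    covariates: list[str]
    eta: np.ndarray
    se_jackknife: np.ndarray | None
    linpred: pd.Series  # exp(z'eta) per observation (d = 1) row, indexed like data
    converged: bool = True


@dataclass
class VisitWeights:
    """Per-measurement weights at the three stages of the published recipe."""

    index: pd.Index  # row index of the observation rows in the panel frame
    raw: np.ndarray  # 1 / exp(z'eta)
    normalised: np.ndarray  # raw - mean(raw) + 1
    final: np.ndarray  # shifted one visit later; baseline weight = 1
    n_discarded: int = 0  # last-visit normalised weights dropped by the shift

    def as_series(self) -> pd.Series:
        return pd.Series(self.final, index=self.index, name="iivw_weight")


def _breslow_polish(
    z: np.ndarray, dur: np.ndarray, ev: np.ndarray, eta: np.ndarray, steps: int = 8
) -> np.ndarray:
    """Newton-refine a Cox estimate to the exact Breslow partial-likelihood root.

    Risk sets are on the gap-time scale; suffix sums over durations sorted
    ascending give S0 = sum(w), S1 = sum(w z), S2 = sum(w z z') over each
    risk set, with ties entering the risk set together (Breslow).
    """
    order = np.argsort(dur, kind="stable")
    dur_s, z_s, ev_s = dur[order], z[order], ev[order]
    event_pos = np.searchsorted(dur_s, dur_s[ev_s == 1], side="left")
    z_events = z_s[ev_s == 1]
    for _ in range(steps):
        w = np.exp(z_s @ eta)
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((w[:, None] * z_s)[::-1], axis=0)[::-1]
        S2 = np.cumsum((w[:, None, None] * z_s[:, :, None] * z_s[:, None, :])[::-1], axis=0)[::-1]
        m1 = S1[event_pos] / S0[event_pos, None]
        score = np.sum(z_events - m1, axis=0)
        hess = -np.sum(
            S2[event_pos] / S0[event_pos, None, None] - m1[:, :, None] * m1[:, None, :],
            axis=0,
        )
        step = np.linalg.solve(hess, score)
        eta = eta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    return eta


def _gap_spells(data: PanelDataset, covariates: list[str]) -> pd.DataFrame:
    df = data.data
    spells = df[df["j"] > 0][["id", "gap", "d", *covariates]].copy()
    if spells["d"].sum() < 2:
        raise ValueError("need at least 2 observed gap events to fit the intensity model")
    return spells


def fit_visit_intensity(
    data: PanelDataset,
    covariates: list[str] | None = None,
    jackknife: bool = True,
) -> VisitIntensityFit:
    """Andersen-Gill gap-time model for the visit intensity.

    Every non-baseline row contributes one spell (length = gap, event = d).
    ``jackknife=False`` skips the leave-one-individual-out variance, which
    is only needed when the uncertainty of ``eta`` itself is of interest.
    """
    covariates = list(covariates) if covariates is not None else ["Z"]
    spells = _gap_spells(data, covariates)

    def _eta(frame: pd.DataFrame) -> np.ndarray:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                frame[["gap", "d", *covariates]],
                duration_col="gap",
                event_col="d",
                fit_options={"precision": 1e-9},
            )
        eta = cph.params_.to_numpy()
        return _breslow_polish(
            frame[covariates].to_numpy(dtype=float),
            frame["gap"].to_numpy(dtype=float),
            frame["d"].to_numpy(),
            eta,
        )

    try:
        eta = _eta(spells)
        converged = bool(np.all(np.isfinite(eta)))
    except Exception as exc:
        warnings.warn(f"visit intensity fit failed: {exc}")
        eta = np.full(len(covariates), np.nan)
        converged = False

    se_jk = None
    if jackknife and converged:
        ids = spells["id"].unique()
        reps = np.empty((len(ids), len(covariates)))
        for k, i in enumerate(ids):
            reps[k] = _eta(spells[spells["id"] != i])
        G = len(ids)
        se_jk = np.sqrt((G - 1) / G * np.sum((reps - reps.mean(axis=0)) ** 2, axis=0))

    obs = data.observed()
    lp = np.exp(obs[covariates].to_numpy(dtype=float) @ eta)
    return VisitIntensityFit(
        covariates=covariates,
        eta=eta,
        se_jackknife=se_jk,
        linpred=pd.Series(lp, index=obs.index),
        converged=converged,
    )


def compute_weights(fit: VisitIntensityFit, data: PanelDataset) -> VisitWeights:
    """Normalised, shifted inverse-intensity weights for the outcome model.

    raw = 1/exp(z'eta) per measurement; normalised = raw - mean(raw) + 1
    (mean over all measurement rows, so the normalised weights average to 1
    exactly); the analysis weight of visit j is the normalised weight of
    visit j-1, the baseline visit gets weight 1, and each individual's last
    normalised weight (which describes the step into end of follow-up) is
    discarded.
    """
    if not fit.converged:
        raise ValueError("intensity model did not converge; weights undefined")
    obs = data.observed()
    raw = 1.0 / fit.linpred.loc[obs.index].to_numpy()
    normalised = raw - raw.mean() + 1.0
    final = np.empty_like(normalised)
    ids = obs["id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    final[1:] = normalised[:-1]  # shift one position later within individuals
    final[starts] = 1.0  # baseline measurement
    n_discarded = len(starts)  # one trailing normalised weight dropped per individual
    return VisitWeights(
        index=obs.index, raw=raw, normalised=normalised, final=final, n_discarded=n_discarded
    )


def fit_weighted_marginal(data: PanelDataset, weights: VisitWeights) -> FitResult:
    """Weighted marginal model for the outcome with cluster-robust variance.

    With an identity link and independence working correlation the weighted
    estimating equations reduce to weighted least squares of y on
    (1, Z, t); the sandwich variance is clustered on individual.
    """
    obs = data.observed()
    w = weights.as_series().loc[obs.index].to_numpy()
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    X = sm.add_constant(obs[["Z", "t"]].to_numpy(), has_constant="add")
    names = ["alpha0", "alpha1", "alpha2"]
    try:
        res = sm.WLS(obs["y"].to_numpy(), X, weights=w).fit()
        rob = res.get_robustcov_results(cov_type="cluster", groups=obs["id"].to_numpy())
        est = dict(zip(names, rob.params))
        se = dict(zip(names, rob.bse))
        return FitResult(
            method="E",
            estimates=est,
            se=se,
            vcov=np.asarray(rob.cov_params()),
            loglik=np.nan,
            converged=bool(np.all(np.isfinite(rob.params))),
        )
    except Exception as exc:
        warnings.warn(f"weighted marginal fit failed: {exc}")
        nanp = {k: np.nan for k in names}
        return FitResult(method="E", estimates=dict(nanp), se=dict(nanp), converged=False)


def fit_iivw(
    data: PanelDataset,
    covariates: list[str] | None = None,
    jackknife: bool = False,
) -> FitResult:
    """Convenience wrapper running the full two-stage Model E pipeline."""
    fit = fit_visit_intensity(data, covariates, jackknife=jackknife)
    if not fit.converged:
        nanp = {k: np.nan for k in ["alpha0", "alpha1", "alpha2"]}
        return FitResult(method="E", estimates=dict(nanp), se=dict(nanp), converged=False)
    weights = compute_weights(fit, data)
    result = fit_weighted_marginal(data, weights)
    result.extra["eta"] = dict(zip(fit.covariates, fit.eta))
    result.extra["weights"] = weights
    return result
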