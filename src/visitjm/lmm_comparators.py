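"""Random-intercept linear mixed models with visit-count adjustments.

Three comparators share the outcome equation
``y_ij = alpha0 + alpha1*Z_i + alpha2*t_ij [+ alpha3*count] + v_i + eps_ij``:

* Model D ignores the observation process (``adjustment='none'``);
* Model B adds the individual's total number of measurements, centred on
  the grand mean across individuals (``'total_count_centred'``);
* Model C adds the running number of measurements up to and including the
  current one (``'cumulative_count'``), a time-varying covariate.

All models are estimated by full maximum likelihood (not REML), via
``statsmodels`` MixedLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .results import FitResult
from .simulate import PanelDataset

__all__ = ["LmmSpec", "build_count_covariates", "fit_lmm"]

_ADJUSTMENTS = ("none", "total_count_centred", "cumulative_count")
_MODEL_LABEL = {"none": "D", "total_count_centred": "B", "cumulative_count": "C"}


@dataclass(frozen=True)
class LmmSpec:
    adjustment: str = "none"

    def __post_init__(self) -> None:
        if self.adjustment not in _ADJUSTMENTS:
            raise ValueError(f"adjustment must be one of {_ADJUSTMENTS}")


def build_count_covariates(data: PanelDataset, spec: LmmSpec) -> pd.DataFrame:
    """Observation rows (d = 1) augmented with the requested count covariate.

    ``total_count_centred`` adds ``n_i - mean_i(n_i)`` (constant within
    individual, grand mean over individuals); ``cumulative_count`` adds the
    running count of measurements including the current one (1, 2, 3, ...).
    """
    obs = data.observed().copy()
    if spec.adjustment == "total_count_centred":
        counts = obs.groupby("id")["t"].transform("size").astype(float)
        per_ind = obs.groupby("id").size().astype(float)
        obs["count"] = counts - per_ind.mean()
    elif spec.adjustment == "cumulative_count":
        obs["count"] = obs.groupby("id").cumcount().astype(float) + 1.0
    return obs


def fit_lmm(data: PanelDataset, spec: LmmSpec = LmmSpec()) -> FitResult:
    """ML fit of the random-intercept model selected by ``spec``."""
    obs = build_count_covariates(data, spec)
    names = ["alpha0", "alpha1", "alpha2"]
    cols = ["Z", "t"]
    degenerate_count = False
    if spec.adjustment != "none":
        if obs["count"].std() == 0.0:
            # e.g. all visit counts equal: the centred covariate is identically
            # zero and the adjusted model collapses to the plain one
            degenerate_count = True
        else:
            cols.append("count")
            names.append("alpha3")
    exog = sm.add_constant(obs[cols].to_numpy(), has_constant="add")
    label = _MODEL_LABEL[spec.adjustment]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(obs["y"].to_numpy(), exog, groups=obs["id"].to_numpy())
            res = model.fit(reml=False, maxiter=500)
        fe = dict(zip(names, res.fe_params))
        fe_se = dict(zip(names, res.bse_fe))
        if degenerate_count:
            fe["alpha3"] = 0.0
            fe_se["alpha3"] = np.nan
        s2v = float(np.asarray(res.cov_re).ravel()[0])
        s2e = float(res.scale)
        est = {**fe, "sigma2_v": s2v, "sigma2_eps": s2e}
        se = {**fe_se, "sigma2_v": np.nan, "sigma2_eps": np.nan}
        k = len(names)
        vcov = np.asarray(res.cov_params())[:k, :k]
        converged = bool(res.converged) and np.all(np.isfinite(list(fe.values())))
        return FitResult(
            method=label,
            estimates=est,
            se=se,
            vcov=vcov,
            loglik=float(res.llf),
            converged=converged,
        )
    except Exception as exc:
        warnings.warn(f"mixed model fit failed: {exc}")
        nan_names = names + ["sigma2_v", "sigma2_eps"]
        nanp = {k: np.nan for k in nan_names}
        return FitResult(method=label, estimates=dict(nanp), se=dict(nanp), converged=False)
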