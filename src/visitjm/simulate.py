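"""Data-generating mechanisms for longitudinal data with an informative visiting process.

Two families of mechanisms are implemented:

* a joint model in which a Weibull gap-time intensity for the visiting
  process shares a Gaussian frailty ``u_i`` with the longitudinal outcome
  (association scaled by ``gamma_assoc``), optionally augmented with planned
  yearly visits; and
* Gamma gap-time mechanisms in which the visit intensity depends on
  treatment (and optionally the previous outcome value) but not on a shared
  frailty.

Every individual is observed at baseline (t = 0), accrues visits until an
administrative censoring time ``C ~ Unif(censor_lo, censor_hi)``, and
contributes one final censored gap from the last visit to ``C``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ScenarioConfig",
    "PanelDataset",
    "draw_weibull_gap",
    "simulate_joint_scenario",
    "simulate_gamma_scenario",
    "simulate_scenario",
]

_DGM_KINDS = ("joint", "gamma", "gamma_lagged_y", "joint_regular_visits")

#: canonical column order of a panel dataset on disk
PANEL_COLUMNS = ["id", "j", "t", "gap", "d", "y", "Z", "C"]


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulation scenario.

    Defaults are the shared settings used across scenarios: 200 individuals,
    a binary treatment drawn with probability 0.5, Weibull shape 1.05,
    administrative censoring drawn from Unif(5, 10) years, and the
    longitudinal fixed effects (0, 1, 0.2) with variance components
    (sigma2_u, sigma2_v, sigma2_eps) = (1, 0.5, 1).
    """

    dgm_kind: str = "joint"
    n_individuals: int = 200
    lam: float = 0.30  # Weibull scale of the visit intensity
    p: float = 1.05  # Weibull shape
    beta: float = 1.0  # visit-process treatment coefficient
    alpha0: float = 0.0
    alpha1: float = 1.0
    alpha2: float = 0.2
    gamma_assoc: float = 0.0  # association between visiting and outcome
    sigma2_u: float = 1.0  # frailty variance (visit process)
    sigma2_v: float = 0.5  # outcome random-intercept variance
    sigma2_eps: float = 1.0  # residual variance
    psi: float = 0.0  # Gamma-DGM treatment association
    omega: float | None = None  # lagged-outcome coefficient (gamma_lagged_y)
    sigma2_xi: float = 0.1  # variance of the Gamma-DGM log-scale frailty
    gamma_shape: float = 2.0  # shape of the Gamma gap distribution
    censor_lo: float = 5.0
    censor_hi: float = 10.0
    regular_interval: float = 1.0  # planned-visit spacing (years)
    treatment_prob: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dgm_kind not in _DGM_KINDS:
            raise ValueError(f"unknown dgm_kind {self.dgm_kind!r}; expected one of {_DGM_KINDS}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (self.lam > 0 and self.p > 0 and self.gamma_shape > 0):
            raise ValueError("lam, p and gamma_shape must be positive")
        for name in ("sigma2_u", "sigma2_v", "sigma2_eps", "sigma2_xi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.censor_lo < self.censor_hi:
            raise ValueError("censor_lo must be < censor_hi")
        if not 0.0 <= self.treatment_prob <= 1.0:
            raise ValueError("treatment_prob must lie in [0, 1]")
        if self.dgm_kind == "gamma_lagged_y" and self.omega is None:
            raise ValueError("dgm_kind 'gamma_lagged_y' requires omega")

    # -- flat key-value (YAML) round trip ---------------------------------
    @classmethod
    def from_yaml(cls, path_or_stream) -> "ScenarioConfig":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("scenario config must be a flat mapping")
        if "lambda" in raw:  # allow the mathematical name on disk
            raw["lam"] = raw.pop("lambda")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path=None) -> str:
        out = {}
        for f in fields(self):
            val = getattr(self, f.name)
            if val is None:
                continue
            out["lambda" if f.name == "lam" else f.name] = val
        text = yaml.safe_dump(out, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


@dataclass
class PanelDataset:
    """Long-format visit data plus (optional) per-individual latent values.

    ``data`` has one row per recorded measurement (``d = 1``) and one final
    censored gap row per individual (``d = 0``, no outcome).  ``latent``
    stores the generating random effects ``u, v, xi`` for testing; it is
    never consumed by any estimator.
    """

    data: pd.DataFrame
    latent: pd.DataFrame | None = field(default=None, repr=False)

    def validate(self) -> "PanelDataset":
        """Check the structural invariants; raise ``ValueError`` on violation."""
        df = self.data
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if not df["Z"].isin([0, 1]).all():
            raise ValueError("Z must be binary")
        if (df["y"].notna() != (df["d"] == 1)).any():
            raise ValueError("y must be present iff d = 1")
        for i, g in df.groupby("id", sort=False):
            t = g["t"].to_numpy()
            if not (g["j"].to_numpy() == np.arange(len(g))).all():
                raise ValueError(f"id {i}: j must be 0..n-1")
            if not (t[0] == 0.0 and g["d"].iloc[0] == 1):
                raise ValueError(f"id {i}: first row must be an observed baseline at t = 0")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"id {i}: t must be strictly increasing")
            if not (g["d"].iloc[-1] == 0):
                raise ValueError(f"id {i}: final row must be the censored gap")
            C = g["C"].iloc[0]
            if not np.isclose(g["gap"].iloc[-1], C - t[-2]):
                raise ValueError(f"id {i}: censored gap must equal C - last observed t")
            if not np.isclose(g["gap"].sum(), C):
                raise ValueError(f"id {i}: gaps must sum to C")
            if (g["d"].iloc[1:-1] != 1).any():
                raise ValueError(f"id {i}: interior rows must be observed visits")
        return self

    # -- delimited-text round trip ----------------------------------------
    def to_csv(self, path_or_buf=None):
        return self.data[PANEL_COLUMNS].to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "PanelDataset":
        df = pd.read_csv(path_or_buf)
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel CSV missing columns: {missing}")
        df = df[PANEL_COLUMNS].astype(
            {"id": int, "j": int, "t": float, "gap": float, "d": int, "Z": int, "C": float}
        )
        return cls(data=df)

    @property
    def n_individuals(self) -> int:
        return self.data["id"].nunique()

    def observed(self) -> pd.DataFrame:
        """Rows carrying a measurement (d = 1)."""
        return self.data[self.data["d"] == 1]


def draw_weibull_gap(u, Z, cfg: ScenarioConfig, rng: np.random.Generator):
    """Draw gap time(s) from the Weibull proportional-hazards visit model.

    Uses inversion of the survival function
    ``S(t) = exp(-lam * t**p * exp(beta*Z + u))``:
    ``t = (-log(U) / (lam * exp(beta*Z + u)))**(1/p)`` with U ~ Unif(0, 1).
    ``u`` and ``Z`` may be scalars or broadcastable arrays.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("frailty u must be finite")
    rate = cfg.lam * np.exp(cfg.beta * np.asarray(Z, dtype=float) + u)
    U = rng.uniform(size=np.broadcast(u, rate).shape)
    return (-np.log(U) / rate) ** (1.0 / cfg.p)


def _rng_for(cfg: ScenarioConfig, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    if cfg.seed is None:
        raise ValueError("either pass an rng or set cfg.seed")
    return np.random.default_rng(cfg.seed)


def _assemble(rows: list, latents: list) -> PanelDataset:
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    df["id"] = df["id"].astype(int)
    df["j"] = df["j"].astype(int)
    df["d"] = df["d"].astype(int)
    df["Z"] = df["Z"].astype(int)
    lat = pd.DataFrame(latents, columns=["id", "u", "v", "xi", "Z", "C"])
    return PanelDataset(data=df, latent=lat)


def _outcome(t, Z, shared, v, cfg, rng):
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2_eps), size=np.shape(t))
    return cfg.alpha0 + cfg.alpha1 * Z + cfg.alpha2 * np.asarray(t) + shared + v + eps


def simulate_joint_scenario(cfg: ScenarioConfig, rng=None) -> PanelDataset:
    """Simulate from the shared-frailty joint model.

    Recurrent visit gaps follow the Weibull intensity
    ``r(t) = lam * p * t**(p-1) * exp(beta*Z + u)`` on a gap-time clock;
    outcomes at observed visits follow
    ``y = alpha0 + alpha1*Z + alpha2*t + gamma_assoc*u + v + eps``.
    For ``dgm_kind = 'joint_regular_visits'`` planned visits at multiples of
    ``regular_interval`` (up to C) are merged into the visit schedule; the
    gap-time clock of the frailty-driven process is not reset by a planned
    visit, so planned visits only interleave extra measurement times.
    """
    if cfg.dgm_kind not in ("joint", "joint_regular_visits"):
        raise ValueError(f"simulate_joint_scenario cannot handle dgm_kind {cfg.dgm_kind!r}")
    rng = _rng_for(cfg, rng)
    rows: list = []
    latents: list = []
    su, sv = np.sqrt(cfg.sigma2_u), np.sqrt(cfg.sigma2_v)
    for i in range(cfg.n_individuals):
        Z = int(rng.uniform() < cfg.treatment_prob)
        u = rng.normal(0.0, su)
        v = rng.normal(0.0, sv)
        C = rng.uniform(cfg.censor_lo, cfg.censor_hi)
        rate = cfg.lam * np.exp(cfg.beta * Z + u)
        t = 0.0
        times = [0.0]
        while True:
            gap = (-np.log(rng.uniform()) / rate) ** (1.0 / cfg.p)
            if t + gap > C:
                break
            t += gap
            times.append(t)
        if cfg.dgm_kind == "joint_regular_visits":
            planned = np.arange(cfg.regular_interval, C, cfg.regular_interval)
            times = np.unique(np.concatenate([np.asarray(times), planned]))
        times = np.asarray(times)
        ys = _outcome(times, Z, cfg.gamma_assoc * u, v, cfg, rng)
        gaps = np.diff(times, prepend=0.0)
        for j, (tj, gj, yj) in enumerate(zip(times, gaps, ys)):
            rows.append((i, j, tj, gj, 1, yj, Z, C))
        rows.append((i, len(times), C, C - times[-1], 0, np.nan, Z, C))
        latents.append((i, u, v, np.nan, Z, C))
    return _assemble(rows, latents)


def simulate_gamma_scenario(cfg: ScenarioConfig, rng=None) -> PanelDataset:
    """Simulate with Gamma-distributed visit gaps and no shared frailty.

    Gaps are Gamma(shape = gamma_shape, scale = exp(-psi*beta*Z [+ omega*y_prev]
    + xi)) with an individual-level log-scale perturbation ``xi ~ N(0,
    sigma2_xi)``.  Outcomes follow the same longitudinal equation as the
    joint mechanism but without the shared-frailty term.
    """
    if cfg.dgm_kind not in ("gamma", "gamma_lagged_y"):
        raise ValueError(f"simulate_gamma_scenario cannot handle dgm_kind {cfg.dgm_kind!r}")
    lagged = cfg.dgm_kind == "gamma_lagged_y"
    if lagged and cfg.omega is None:
        raise ValueError("gamma_lagged_y requires omega")
    rng = _rng_for(cfg, rng)
    rows: list = []
    latents: list = []
    sv, sxi = np.sqrt(cfg.sigma2_v), np.sqrt(cfg.sigma2_xi)
    for i in range(cfg.n_individuals):
        Z = int(rng.uniform() < cfg.treatment_prob)
        v = rng.normal(0.0, sv)
        xi = rng.normal(0.0, sxi)
        C = rng.uniform(cfg.censor_lo, cfg.censor_hi)
        base_log_scale = -cfg.psi * cfg.beta * Z + xi
        t = 0.0
        y = float(_outcome(0.0, Z, 0.0, v, cfg, rng))
        rows.append((i, 0, 0.0, 0.0, 1, y, Z, C))
        j = 1
        while True:
            log_scale = base_log_scale + (cfg.omega * y if lagged else 0.0)
            gap = rng.gamma(cfg.gamma_shape, np.exp(log_scale))
            if t + gap > C:
                break
            t += gap
            y = float(_outcome(t, Z, 0.0, v, cfg, rng))
            rows.append((i, j, t, gap, 1, y, Z, C))
            j += 1
        rows.append((i, j, C, C - t, 0, np.nan, Z, C))
        latents.append((i, np.nan, v, xi, Z, C))
    return _assemble(rows, latents)


def simulate_scenario(cfg: ScenarioConfig, rng=None) -> PanelDataset:
    """Dispatch to the mechanism selected by ``cfg.dgm_kind``."""
    if cfg.dgm_kind in ("joint", "joint_regular_visits"):
        return simulate_joint_scenario(cfg, rng)
    return simulate_gamma_scenario(cfg, rng)
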