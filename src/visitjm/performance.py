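"""Monte Carlo simulation-study engine and performance measures.

Runs K replicates of scenario x method cells, collects estimates and model
standard errors, and summarises bias, empirical SE, coverage of nominal 95%
Wald intervals and MSE, each with its Monte Carlo standard error following
the standard simulation-study calculus:

    MCSE(bias)     = empSE / sqrt(K)
    MCSE(empSE)    = empSE / sqrt(2 (K - 1))
    MCSE(coverage) = sqrt(c (1 - c) / K)
    MCSE(mse)      = sd((est - truth)^2) / sqrt(K)

Non-convergent fits are recorded and excluded cell-wise; the convergence
rate is reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .iivw import fit_iivw
from .joint_model import fit_joint_model
from .lmm_comparators import LmmSpec, fit_lmm
from .simulate import PanelDataset, ScenarioConfig, simulate_scenario

__all__ = [
    "run_study",
    "summarise",
    "truth_from_config",
    "required_replications",
    "coverage_mcse",
    "fit_method",
    "scenario_descriptives",
]

METHODS = ("A", "B", "C", "D", "E")


def required_replications(variance: float, mcse_target: float) -> int:
    """Smallest K with MCSE(bias) = sqrt(variance / K) <= mcse_target."""
    if variance < 0 or mcse_target <= 0:
        raise ValueError("variance must be >= 0 and mcse_target > 0")
    return int(np.ceil(variance / mcse_target**2))


def coverage_mcse(coverage: float, K: int) -> float:
    """Monte Carlo SE of an estimated coverage proportion."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    return float(np.sqrt(coverage * (1.0 - coverage) / K))


def truth_from_config(cfg: ScenarioConfig) -> dict[str, float]:
    """Generating values of the estimands tracked in the study."""
    truth = {
        "alpha0": cfg.alpha0,
        "alpha1": cfg.alpha1,
        "alpha2": cfg.alpha2,
        "sigma2_v": cfg.sigma2_v,
        "sigma2_eps": cfg.sigma2_eps,
    }
    if cfg.dgm_kind in ("joint", "joint_regular_visits"):
        truth.update(
            {
                "gamma": cfg.gamma_assoc,
                "sigma2_u": cfg.sigma2_u,
                "lambda": cfg.lam,
                "p": cfg.p,
                "beta": cfg.beta,
            }
        )
    return truth


def fit_method(method: str, data: PanelDataset, n_quad: int = 9):
    """Dispatch one of the five estimators by its study label."""
    if method == "A":
        return fit_joint_model(data, n_quad=n_quad)
    if method == "B":
        return fit_lmm(data, LmmSpec("total_count_centred"))
    if method == "C":
        return fit_lmm(data, LmmSpec("cumulative_count"))
    if method == "D":
        return fit_lmm(data, LmmSpec("none"))
    if method == "E":
        return fit_iivw(data)
    raise ValueError(f"unknown method label {method!r}; expected one of {METHODS}")


def replicate_rng(master_seed: int, scenario_index: int, replicate: int) -> np.random.Generator:
    """Counter-based per-replicate stream: reproducible cell by cell."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(scenario_index, replicate))
    return np.random.default_rng(ss)


def run_study(
    scenarios: dict[str, ScenarioConfig],
    methods: tuple[str, ...] = METHODS,
    K: int = 100,
    master_seed: int = 1,
    n_quad: int = 9,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate and fit K replicates for every scenario and method.

    Returns a long replicate-level table with one row per (scenario,
    replicate, method, estimand): columns est, se, converged.  All methods
    within a replicate see the same simulated dataset.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    records = []
    for s_idx, (name, cfg) in enumerate(scenarios.items()):
        for k in range(K):
            rng = replicate_rng(master_seed, s_idx, k)
            data = simulate_scenario(cfg, rng)
            for method in methods:
                fit = fit_method(method, data, n_quad=n_quad)
                for est_name, est in fit.estimates.items():
                    records.append(
                        (name, k, method, est_name, est, fit.se.get(est_name, np.nan),
                         bool(fit.converged))
                    )
            if progress and (k + 1) % 10 == 0:
                print(f"{name}: {k + 1}/{K} replicates", flush=True)
    return pd.DataFrame(
        records, columns=["scenario", "replicate", "method", "estimand", "est", "se", "converged"]
    )


def scenario_descriptives(
    cfg: ScenarioConfig, K: int = 1000, master_seed: int = 1, scenario_index: int = 0
) -> dict[str, float]:
    """Descriptive statistics of a data-generating mechanism over K datasets.

    Returns the median (and quartiles) across datasets of the number of
    measurements, plus medians of the per-individual measurement counts and
    of the observed gap times, both pooled over all datasets.
    """
    sizes = np.empty(K)
    counts: list[int] = []
    gaps: list[np.ndarray] = []
    for k in range(K):
        rng = replicate_rng(master_seed, scenario_index, k)
        data = simulate_scenario(cfg, rng)
        obs = data.observed()
        sizes[k] = len(obs)
        counts.extend(obs.groupby("id").size().tolist())
        df = data.data
        gaps.append(df.loc[(df["j"] > 0) & (df["d"] == 1), "gap"].to_numpy())
    pooled = np.concatenate(gaps)
    q1, q3 = np.percentile(sizes, [25, 75])
    return {
        "median_sample_size": float(np.median(sizes)),
        "sample_size_q1": float(q1),
        "sample_size_q3": float(q3),
        "median_measurements_per_individual": float(np.median(counts)),
        "median_gap": float(np.median(pooled)),
        "gap_q1": float(np.percentile(pooled, 25)),
        "gap_q3": float(np.percentile(pooled, 75)),
        "K": K,
    }


def summarise(
    results: pd.DataFrame,
    truth: dict[str, float] | dict[str, dict[str, float]],
    z: float = 1.96,
) -> pd.DataFrame:
    """Performance measures per (scenario, method, estimand) cell.

    ``truth`` maps estimand name to generating value, or scenario name to
    such a mapping when scenarios have different truths.  Estimands absent
    from the truth mapping are skipped; non-converged replicates are
    excluded and counted in ``convergence_rate``.
    """
    per_scenario = truth and isinstance(next(iter(truth.values())), dict)
    rows = []
    for (scen, method, est_name), cell in results.groupby(
        ["scenario", "method", "estimand"], sort=False
    ):
        tmap = truth[scen] if per_scenario else truth
        if est_name not in tmap:
            continue
        theta = tmap[est_name]
        if theta is None:
            raise ValueError(f"missing truth for estimand {est_name!r}")
        n_total = len(cell)
        ok = cell[cell["converged"] & cell["est"].notna()]
        Kc = len(ok)
        if Kc < 2:
            raise ValueError(f"need >= 2 converged replicates in cell {(scen, method, est_name)}")
        est = ok["est"].to_numpy()
        se = ok["se"].to_numpy()
        err = est - theta
        bias = err.mean()
        median_bias = float(np.median(est)) - theta
        emp_se = est.std(ddof=1)
        mse = float(np.mean(err**2))
        with np.errstate(invalid="ignore"):
            covered = (np.abs(err) <= z * se).astype(float)
        has_se = np.isfinite(se)
        coverage = float(covered[has_se].mean()) if has_se.any() else np.nan
        K_cov = int(has_se.sum())
        rows.append(
            {
                "scenario": scen,
                "method": method,
                "estimand": est_name,
                "n_converged": Kc,
                "convergence_rate": Kc / n_total,
                "bias": bias,
                "median_bias": median_bias,
                "empirical_se": emp_se,
                "mean_model_se": float(np.nanmean(se)) if has_se.any() else np.nan,
                "coverage": coverage,
                "mse": mse,
                "mcse_bias": emp_se / np.sqrt(Kc),
                "mcse_empirical_se": emp_se / np.sqrt(2.0 * (Kc - 1)),
                "mcse_coverage": coverage_mcse(coverage, K_cov) if K_cov else np.nan,
                "mcse_mse": float(np.std(err**2, ddof=1)) / np.sqrt(Kc),
            }
        )
    return pd.DataFrame(rows)


def format_summary(summary: pd.DataFrame) -> str:
    """Plain-text table of the key performance measures."""
    cols = [
        "scenario", "method", "estimand", "bias", "mcse_bias",
        "coverage", "mcse_coverage", "mse", "convergence_rate",
    ]
    return summary[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}")
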