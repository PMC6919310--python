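"""Common container for fitted-model output, shared by all five estimators."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Point estimates, standard errors and bookkeeping for one fitted model.

    ``estimates`` and ``se`` are name-aligned dictionaries; ``vcov`` (when
    available) is ordered like ``names``.  ``converged`` is False whenever
    the optimiser failed or the observed information was not positive
    definite; callers must treat such fits as missing, never as exceptions.
    """

    method: str
    estimates: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray | None = None
    loglik: float = np.nan
    converged: bool = True
    n_quad: int | None = None
    iterations: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.estimates)

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Normal-based confidence interval for one parameter."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        est, se = self.estimates[name], self.se[name]
        return est - z * se, est + z * se

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "estimates": self.estimates,
            "se": self.se,
            "vcov": None if self.vcov is None else np.asarray(self.vcov).tolist(),
            "loglik": None if np.isnan(self.loglik) else float(self.loglik),
            "converged": bool(self.converged),
            "n_quad": self.n_quad,
            "iterations": int(self.iterations),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "FitResult":
        if isinstance(path_or_text, str) and path_or_text.lstrip().startswith("{"):
            payload = json.loads(path_or_text)
        else:
            with open(path_or_text) as fh:
                payload = json.load(fh)
        vcov = payload.get("vcov")
        return cls(
            method=payload["method"],
            estimates={k: float(v) for k, v in payload["estimates"].items()},
            se={k: float(v) for k, v in payload["se"].items()},
            vcov=None if vcov is None else np.asarray(vcov, dtype=float),
            loglik=np.nan if payload.get("loglik") is None else float(payload["loglik"]),
            converged=bool(payload["converged"]),
            n_quad=payload.get("n_quad"),
            iterations=int(payload.get("iterations", 0)),
        )
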