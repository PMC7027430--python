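"""Shared result containers for every fitted model family."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class FitResult:
    """Fit summary shared by all model families.

    AIC and BIC use the one formula ``-2 loglik + penalty * n_params`` for
    every family, so cross-family comparisons are well defined.
    """

    family: str
    params: Any
    param_names: list[str]
    estimates: np.ndarray
    loglik: float
    n_params: int
    n_obs: int
    se: np.ndarray
    ci: np.ndarray  # (k, 2) lower/upper
    ci_level: float
    converged: bool
    n_restarts_used: int = 0
    data: Any = field(default=None, repr=False)
    extra: dict = field(default_factory=dict, repr=False)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.n_params

    def coef(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def to_dict(self) -> dict:
        """Machine-readable key-value report."""
        return {
            "family": self.family,
            "converged": bool(self.converged),
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "ci_level": float(self.ci_level),
            "coefficients": {
                name: {
                    "estimate": float(est),
                    "se": float(se),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                }
                for name, est, se, (lo, hi) in zip(
                    self.param_names, self.estimates, self.se, self.ci
                )
            },
        }

    def summary(self) -> str:
        lines = [
            f"Model family: {self.family}",
            f"Observations: {self.n_obs}   Parameters: {self.n_params}",
            f"Log-likelihood: {self.loglik:.4f}   AIC: {self.aic:.4f}   "
            f"BIC: {self.bic:.4f}",
            f"Converged: {self.converged}",
            "",
            f"{'coef':<12}{'estimate':>12}{'SE':>12}"
            f"{f'{self.ci_level:.0%} CI':>24}",
        ]
        for name, est, se, (lo, hi) in zip(
            self.param_names, self.estimates, self.se, self.ci
        ):
            lines.append(
                f"{name:<12}{est:>12.4f}{se:>12.4f}{f'({lo:.4f}, {hi:.4f})':>24}"
            )
        return "\n".join(lines)


@dataclass
class GofResult:
    """Goodness-of-fit statistic with its chi-square reference."""

    statistic: float
    df: int
    p_value: float
    method: str
    grouped_table: Any = None
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.method}: statistic = {self.statistic:.4f}, "
            f"df = {self.df}, p-value = {self.p_value:.4f}"
        )
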