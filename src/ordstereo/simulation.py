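"""Data generators and the misspecification simulation engine.

Four study cases, each a grid of named scenarios:

* **case1** — data truly follow an interaction-free ordered stereotype
  model; an interaction term is added to both the linear and the
  stereotype fits and ``H0: beta_12 = 0`` is tested at 5%.  Treating the
  1..q codes as continuous makes the linear model reject far too often,
  while the stereotype fit stays near nominal size.
* **case1_unbalanced** — same design at q = 5 with intercept sets that
  skew the response toward the low, middle, or high categories.
* **case2** — main-effect size and power, comparing stereotype,
  proportional odds, and linear fits when the truth is a stereotype or a
  proportional odds model (scenario labels S..../P....).
* **case3** — truth is a baseline-category logit; stereotype and
  proportional odds fits are compared by AIC.
* **case4** — truth is the interaction-free linear model; the ordinal
  fits should keep nominal size (robustness check).

Every generator takes an explicit ``numpy`` Generator, so identical
(scenario, reps, seed) inputs give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .comparison import coef_test, fit_linear, fit_proportional_odds
from .data import OrdinalDataset
from .stereotype import StereotypeParams, fit_stereotype, stereotype_probabilities

__all__ = [
    "Scenario",
    "ExperimentResult",
    "gen_stereotype",
    "gen_pom",
    "gen_baseline_logit",
    "gen_linear_ordinalized",
    "generate",
    "scenario_registry",
    "run_rejection_experiment",
    "run_aic_experiment",
]


@dataclass
class Scenario:
    """A named generative configuration."""

    case_id: str
    label: str
    true_family: str  # stereotype | proportional_odds | baseline_logit | linear
    q: int
    n: int
    covariate_spec: list[tuple]  # ("normal", mu, sigma) or ("bernoulli", pi)
    alpha: np.ndarray | None = None
    phi: np.ndarray | None = None
    beta: np.ndarray | None = None
    beta_mat: np.ndarray | None = None
    interaction_in_truth: bool = False
    alpha_reconstructed: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "phi", "beta"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if self.beta_mat is not None:
            self.beta_mat = np.atleast_2d(np.asarray(self.beta_mat, dtype=float))
        if self.true_family == "stereotype":
            if self.phi is None or self.phi.shape[0] != self.q:
                raise ValueError("stereotype scenario needs a length-q phi")
            if self.alpha is None or self.alpha.shape[0] != self.q:
                raise ValueError("stereotype scenario needs a length-q alpha")

    @property
    def p(self) -> int:
        return len(self.covariate_spec)


def _draw_covariates(spec: list[tuple], n: int, rng: np.random.Generator) -> np.ndarray:
    cols = []
    for item in spec:
        kind = item[0]
        if kind == "normal":
            _, mu, var = item
            cols.append(rng.normal(mu, np.sqrt(var), size=n))
        elif kind == "bernoulli":
            _, pi = item
            cols.append(rng.binomial(1, pi, size=n).astype(float))
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    return np.column_stack(cols)


def _sample_categorical(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of one category per row (returns 1-based codes)."""
    cum = np.cumsum(theta, axis=1)
    u = rng.random(theta.shape[0])
    return 1 + (u[:, None] > cum).sum(axis=1)


def gen_stereotype(scenario: Scenario, rng: np.random.Generator) -> OrdinalDataset:
    """Sample from an ordered stereotype model."""
    X = _draw_covariates(scenario.covariate_spec, scenario.n, rng)
    params = StereotypeParams(scenario.alpha, scenario.phi, scenario.beta)
    theta = stereotype_probabilities(params, X)
    y = _sample_categorical(theta, rng)
    return OrdinalDataset(y=y, X=X, q=scenario.q,
                          metadata={"scenario": scenario.label,
                                    "true_family": "stereotype"})


def gen_pom(scenario: Scenario, rng: np.random.Generator) -> OrdinalDataset:
    """Sample from a cumulative-logit proportional odds model.

    Orientation: ``logit P(Y <= k | x) = alpha_k + beta' x`` with strictly
    increasing cut intercepts ``alpha_1 < ... < alpha_{q-1}``.
    """
    alpha = np.asarray(scenario.alpha, dtype=float)
    if alpha.shape[0] != scenario.q - 1 or np.any(np.diff(alpha) <= 0):
        raise ValueError("proportional odds scenario needs q-1 strictly increasing cuts")
    X = _draw_covariates(scenario.covariate_spec, scenario.n, rng)
    eta = alpha[None, :] + (X @ scenario.beta)[:, None]
    cum = np.column_stack([special.expit(eta), np.ones(scenario.n)])
    u = rng.random(scenario.n)
    y = 1 + (u[:, None] > cum).sum(axis=1)
    return OrdinalDataset(y=y, X=X, q=scenario.q,
                          metadata={"scenario": scenario.label,
                                    "true_family": "proportional_odds"})


def gen_baseline_logit(scenario: Scenario, rng: np.random.Generator) -> OrdinalDataset:
    """Sample from a baseline-category logit model (softmax of free logits)."""
    alpha = np.asarray(scenario.alpha, dtype=float)  # length q, alpha[0]=0
    B = scenario.beta_mat  # (q, p) with first row 0
    X = _draw_covariates(scenario.covariate_spec, scenario.n, rng)
    eta = alpha[None, :] + X @ B.T
    theta = special.softmax(eta, axis=1)
    y = _sample_categorical(theta, rng)
    return OrdinalDataset(y=y, X=X, q=scenario.q,
                          metadata={"scenario": scenario.label,
                                    "true_family": "baseline_logit"})


def gen_linear_ordinalized(scenario: Scenario, rng: np.random.Generator) -> OrdinalDataset:
    """Sample a Gaussian linear response and cut it into q ordinal levels.

    ``y* = beta' x + eps`` with ``eps ~ N(0, 1)``; the latent response is
    discretized at its empirical ``k/q`` quantiles, giving near-equal level
    frequencies.  Larger latent values never map to a smaller level.
    """
    X = _draw_covariates(scenario.covariate_spec, scenario.n, rng)
    y_star = X @ scenario.beta + rng.normal(size=scenario.n)
    cuts = np.quantile(y_star, np.arange(1, scenario.q) / scenario.q)
    y = 1 + np.searchsorted(cuts, y_star, side="left")
    return OrdinalDataset(
        y=y, X=X, q=scenario.q,
        metadata={"scenario": scenario.label, "true_family": "linear",
                  "discretization": "equal-frequency empirical quantile cuts",
                  "cuts": cuts.tolist()},
    )


_GENERATORS = {
    "stereotype": gen_stereotype,
    "proportional_odds": gen_pom,
    "baseline_logit": gen_baseline_logit,
    "linear": gen_linear_ordinalized,
}


def generate(scenario: Scenario, rng: np.random.Generator) -> OrdinalDataset:
    """Dispatch to the generator of the scenario's true family."""
    return _GENERATORS[scenario.true_family](scenario, rng)


# --------------------------------------------------------------------------
# scenario registry

_CASE1_ALPHA = {
    3: np.array([0.0, -0.6, -1.5]),
    4: np.array([0.0, 0.2, -0.8, -1.2]),
    5: np.array([0.0, -0.1, -0.8, -1.2, -1.6]),
}


def _equal_phi(q: int) -> np.ndarray:
    return np.arange(q) / (q - 1)


_UNBALANCED_ALPHA = {
    "Low": np.array([0.0, 0.2, -1.0, -1.6, -2.5]),
    "Mid": np.array([0.0, 0.2, 1.0, -1.6, -2.5]),
    "High": np.array([0.0, -1.6, -2.5, 0.2, 1.0]),
}

_SCEN_COV = {
    1: [("normal", 0.0, 1.0), ("bernoulli", 0.5)],
    2: [("normal", 0.0, 1.0), ("normal", 0.0, 1.0)],
}

_CASE1_BETAS = [(b1, b2) for b2 in (2.5, 3.0, 3.5, 4.0) for b1 in (0.5, 0.75, 1.0)]
_CASE1_BETAS_S2 = [(b1, b2) for b2 in (2.5, 3.0, 3.5, 4.0) for b1 in (1.0, 2.0, 3.0)]
_UNBAL_BETAS = [(0.5, 2.5), (0.75, 3.0), (1.0, 4.0)]

_CASE2_PHI = {
    "1": np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    "2": np.array([0.0, 0.2, 0.8, 1.0]),
    "3": np.array([0.0, 0.3, 0.998, 1.0]),
}
_N53 = ("normal", 5.0, 3.0)
_B05 = ("bernoulli", 0.5)


def _stereotype_alpha_for_balance(phi, beta, covariate_spec) -> np.ndarray:
    """Intercepts giving equal expected category frequencies at the covariate means."""
    means = np.array([c[1] if c[0] == "normal" else c[1] for c in covariate_spec])
    t_bar = float(means @ np.asarray(beta, dtype=float))
    return -np.asarray(phi, dtype=float) * t_bar


def _pom_alpha_for_balance(q, beta, covariate_spec) -> np.ndarray:
    means = np.array([c[1] if c[0] == "normal" else c[1] for c in covariate_spec])
    t_bar = float(means @ np.asarray(beta, dtype=float))
    k = np.arange(1, q)
    return special.logit(k / q) - t_bar


def _baseline_alpha_for_balance(beta_mat, covariate_spec) -> np.ndarray:
    means = np.array([c[1] if c[0] == "normal" else c[1] for c in covariate_spec])
    return -(beta_mat @ means)


def scenario_registry(case_id: str, n: int = 500) -> list[Scenario]:
    """The printed scenario grids of each simulation case.

    Case 2 and Case 3 intercepts are reconstructed (equal expected marginal
    frequencies at the covariate means) and flagged ``alpha_reconstructed``.
    """
    out: list[Scenario] = []
    if case_id == "case1":
        for scen, betas in ((1, _CASE1_BETAS), (2, _CASE1_BETAS_S2)):
            for q in (3, 4, 5):
                for b1, b2 in betas:
                    out.append(Scenario(
                        case_id="case1",
                        label=f"C1-S{scen}-q{q}-b({b1:g},{b2:g})",
                        true_family="stereotype", q=q, n=n,
                        covariate_spec=_SCEN_COV[scen],
                        alpha=_CASE1_ALPHA[q], phi=_equal_phi(q),
                        beta=np.array([b1, b2]),
                        metadata={"scenario_number": scen},
                    ))
    elif case_id == "case1_unbalanced":
        for scen in (1, 2):
            for name, alpha in _UNBALANCED_ALPHA.items():
                for b1, b2 in _UNBAL_BETAS:
                    out.append(Scenario(
                        case_id="case1_unbalanced",
                        label=f"C1U-S{scen}-{name}-b({b1:g},{b2:g})",
                        true_family="stereotype", q=5, n=n,
                        covariate_spec=_SCEN_COV[scen],
                        alpha=alpha, phi=_equal_phi(5),
                        beta=np.array([b1, b2]),
                        metadata={"scenario_number": scen, "unbalance": name},
                    ))
    elif case_id == "case2":
        q = 4

        def add_s(label, cov, phi_code, beta):
            phi = _CASE2_PHI[phi_code]
            alpha = _stereotype_alpha_for_balance(phi, beta, cov)
            out.append(Scenario(
                case_id="case2", label=label, true_family="stereotype",
                q=q, n=n, covariate_spec=cov, alpha=alpha, phi=phi,
                beta=np.asarray(beta, dtype=float), alpha_reconstructed=True,
            ))

        def add_p(label, cov, beta):
            alpha = _pom_alpha_for_balance(q, beta, cov)
            out.append(Scenario(
                case_id="case2", label=label, true_family="proportional_odds",
                q=q, n=n, covariate_spec=cov, alpha=alpha,
                beta=np.asarray(beta, dtype=float), alpha_reconstructed=True,
            ))

        add_s("S1111", [_N53], "1", [0.0])
        add_s("S1112", [_N53], "1", [0.20])
        for c, phi_code in (("1", "1"), ("2", "2"), ("3", "3")):
            for d, b1 in enumerate((0.15, 0.25, 0.50, 1.00), start=1):
                add_s(f"S21{c}{d}", [_N53, _N53], phi_code, [b1, 0.0])
        for c, phi_code in (("1", "1"), ("2", "2"), ("3", "3")):
            for d, b1 in enumerate((0.15, 0.25, 0.50, 1.00), start=1):
                add_s(f"S22{c}{d}", [_B05, _N53], phi_code, [b1, 0.0])
        add_p("P1111", [_N53], [0.0])
        add_p("P1112", [_N53], [0.15])
        for d, b1 in enumerate((0.15, 0.25, 0.50, 1.00), start=1):
            add_p(f"P211{d}", [_N53, _N53], [b1, 0.0])
    elif case_id == "case3":
        q = 4
        cov = [_N53, _N53]
        grids = {
            1: ([0.0, 0.25, 0.50, 0.8], [0.0, 0.5, -0.05, -0.5]),
            2: ([0.0, 0.25, 0.50, 0.8], [0.0, 0.5, -0.2, -0.5]),
            3: ([0.0, 0.25, 0.50, 0.8], [0.0, -0.2, -0.4, -0.5]),
            4: ([0.0, 2.0, 2.1, 1.9], [0.0, 0.5, -0.05, -0.5]),
        }
        for num, (bk1, bk2) in grids.items():
            beta_mat = np.column_stack([bk1, bk2])  # (q, 2), first row zero
            alpha = _baseline_alpha_for_balance(beta_mat, cov)
            out.append(Scenario(
                case_id="case3", label=f"C3-{num}-n{n}",
                true_family="baseline_logit", q=q, n=n, covariate_spec=cov,
                alpha=alpha, beta_mat=beta_mat, alpha_reconstructed=True,
                metadata={"scenario_number": num},
            ))
    elif case_id == "case4":
        for q in (3, 4, 5):
            for b1, b2 in _CASE1_BETAS:
                out.append(Scenario(
                    case_id="case4", label=f"C4-S1-q{q}-b({b1:g},{b2:g})",
                    true_family="linear", q=q, n=n,
                    covariate_spec=_SCEN_COV[1],
                    beta=np.array([b1, b2]),
                ))
    else:
        raise KeyError(f"unknown case_id {case_id!r}")
    return out


def get_scenario(case_id: str, label: str, n: int = 500) -> Scenario:
    for sc in scenario_registry(case_id, n=n):
        if sc.label == label:
            return sc
    raise KeyError(f"no scenario {label!r} in {case_id}")


# --------------------------------------------------------------------------
# experiments

@dataclass
class ExperimentResult:
    """Per-family rejection or AIC-preference percentages with MC error."""

    scenario_label: str
    reps: int
    level: float
    rates: dict[str, float]          # percent
    mc_se: dict[str, float]          # percent
    n_redrawn: int
    seed: int | None
    unreliable: bool = False

    def as_rows(self) -> list[dict]:
        return [
            {"scenario": self.scenario_label, "family": fam, "reps": self.reps,
             "rate_pct": round(self.rates[fam], 2), "mc_se_pct": round(self.mc_se[fam], 2),
             "level": self.level, "seed": self.seed, "n_redrawn": self.n_redrawn,
             "unreliable": self.unreliable}
            for fam in self.rates
        ]


def _mc_se(rate_pct: float, reps: int) -> float:
    r = rate_pct / 100.0
    return 100.0 * float(np.sqrt(r * (1.0 - r) / reps))


def _stereotype_lrt_pvalue(data_full, data_null, n_restarts, seed):
    full = fit_stereotype(data_full, n_restarts=n_restarts, seed=seed, tol=1e-6)
    null = fit_stereotype(data_null, n_restarts=n_restarts, seed=seed, tol=1e-6)
    if not (full.converged and null.converged):
        return None
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    return float(stats.chi2.sf(stat, 1))


def _pom_lrt_pvalue(data_full, data_null):
    full = fit_proportional_odds(data_full)
    null = fit_proportional_odds(data_null)
    if not (full.converged and null.converged):
        return None
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    return float(stats.chi2.sf(stat, 1))


def run_rejection_experiment(
    scenario: Scenario,
    fitted_families: list[str],
    reps: int,
    test_coef: str | None = None,
    level: float = 0.05,
    seed: int | None = None,
    n_restarts: int = 2,
) -> ExperimentResult:
    """Monte-Carlo rejection rate of ``H0: tested coefficient = 0``.

    For interaction designs (``test_coef="x1:x2"``, the default in cases 1
    and 4) each family is fitted with the product term added; the linear
    model uses the two-sided t-test, the multinomial families a 1-df
    likelihood-ratio test.  Replicates where any requested fit fails to
    converge are redrawn and counted; more than 5% redraws flags the
    result unreliable.
    """
    if test_coef is None:
        test_coef = "x1:x2" if scenario.case_id in (
            "case1", "case1_unbalanced", "case4") else "x1"
    rng = np.random.default_rng(seed)
    rejects = {fam: 0 for fam in fitted_families}
    n_redrawn = 0
    max_redraws = max(int(np.ceil(0.05 * reps)), 5)
    done = 0
    while done < reps:
        data = generate(scenario, rng)
        pvals: dict[str, float] = {}
        failed = False
        for fam in fitted_families:
            if test_coef == "x1:x2":
                if fam == "linear":
                    fit = fit_linear(data, with_interaction=True)
                    pv = fit.extra["pvalues"]["x1:x2"]
                elif fam == "stereotype":
                    pv = _stereotype_lrt_pvalue(
                        data.with_interaction(), data, n_restarts, seed)
                elif fam == "proportional_odds":
                    pv = _pom_lrt_pvalue(data.with_interaction(), data)
                else:
                    raise ValueError(f"unsupported family {fam!r} for interaction test")
            else:
                null_data = data.drop_column(test_coef)
                if fam == "linear":
                    fit = fit_linear(data)
                    pv = coef_test(fit, test_coef, method="wald")["p_value"]
                elif fam == "stereotype":
                    full = fit_stereotype(data, n_restarts=n_restarts, seed=seed,
                                          tol=1e-6)
                    if not full.converged:
                        pv = None
                    else:
                        pv = coef_test(full, test_coef, method="lrt")["p_value"]
                elif fam == "proportional_odds":
                    pv = _pom_lrt_pvalue(data, null_data)
                else:
                    raise ValueError(f"unsupported family {fam!r}")
            if pv is None:
                failed = True
                break
            pvals[fam] = pv
        if failed:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                break
            continue
        for fam, pv in pvals.items():
            rejects[fam] += pv < level
        done += 1

    effective = max(done, 1)
    rates = {fam: 100.0 * rejects[fam] / effective for fam in fitted_families}
    return ExperimentResult(
        scenario_label=scenario.label, reps=done, level=level,
        rates=rates, mc_se={fam: _mc_se(rates[fam], effective) for fam in rates},
        n_redrawn=n_redrawn, seed=seed,
        unreliable=n_redrawn > 0.05 * reps,
    )


def run_aic_experiment(
    scenario: Scenario,
    reps: int,
    seed: int | None = None,
    n_restarts: int = 2,
) -> ExperimentResult:
    """Percentage of replicates where the stereotype fit has lower AIC
    than the proportional odds fit (ties count as "not lower")."""
    if scenario.true_family != "baseline_logit":
        raise ValueError("the AIC-preference experiment expects a baseline-logit truth")
    rng = np.random.default_rng(seed)
    wins = 0
    n_redrawn = 0
    max_redraws = max(int(np.ceil(0.05 * reps)), 5)
    done = 0
    while done < reps:
        data = generate(scenario, rng)
        stereo = fit_stereotype(data, n_restarts=n_restarts, seed=seed, tol=1e-6)
        pom = fit_proportional_odds(data)
        if not (stereo.converged and pom.converged):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                break
            continue
        wins += stereo.aic < pom.aic
        done += 1
    effective = max(done, 1)
    rate = 100.0 * wins / effective
    return ExperimentResult(
        scenario_label=scenario.label, reps=done, level=np.nan,
        rates={"stereotype_aic_preferred": rate},
        mc_se={"stereotype_aic_preferred": _mc_se(rate, effective)},
        n_redrawn=n_redrawn, seed=seed,
        unreliable=n_redrawn > 0.05 * reps,
    )
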