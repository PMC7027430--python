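"""Named, seeded synthetic datasets with their generating truth.

Each fixture wraps a simulation generator into a reproducible dataset plus
the parameter record that generated it, so recovery and diagnostic tests
are fully self-contained.  All fixtures are synthetic.
"""

from __future__ import annotations

import numpy as np

from .data import OrdinalDataset
from .simulation import Scenario, generate
from .stereotype import StereotypeParams, stereotype_probabilities

__all__ = ["fixture_generator", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("balanced_q4_null", "tvsfp_like_2x2", "likert5_feedback_like")


def _tvsfp_like(n: int, rng: np.random.Generator):
    """Synthetic 2x2 factorial design (two binary covariates + interaction),
    q = 4, with stereotype parameters near a school-intervention study's
    collapsed four-level knowledge outcome."""
    params = StereotypeParams(
        alpha=[0.0, 0.023, -0.341, -0.305],
        phi=[0.0, 0.197, 0.878, 1.0],
        beta=[1.052, 0.309, -0.467],
    )
    arms = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    reps = np.bincount(np.arange(n) % 4, minlength=4)
    base = np.repeat(arms, reps, axis=0)
    X = np.column_stack([base, base[:, 0] * base[:, 1]])
    theta = stereotype_probabilities(params, X)
    u = rng.random(n)
    y = 1 + (u[:, None] > np.cumsum(theta, axis=1)).sum(axis=1)
    data = OrdinalDataset(y=y, X=X, q=4, column_names=["cc", "tv", "cc:tv"],
                          metadata={"fixture": "tvsfp_like_2x2", "synthetic": True})
    truth = {"alpha": params.alpha, "phi": params.phi, "beta": params.beta,
             "design": "2x2 factorial with interaction column"}
    return data, truth


def fixture_generator(name: str, seed: int, n: int = 500):
    """Return ``(OrdinalDataset, truth record)`` for a named fixture.

    Deterministic: the same (name, seed, n) always yields identical data.
    """
    rng = np.random.default_rng(seed)
    if name == "balanced_q4_null":
        sc = Scenario(
            case_id="fixture", label=name, true_family="stereotype",
            q=4, n=n,
            covariate_spec=[("normal", 0.0, 1.0), ("bernoulli", 0.5)],
            alpha=[0.0, 0.2, -0.8, -1.2], phi=[0.0, 1 / 3, 2 / 3, 1.0],
            beta=[0.0, 0.0],
        )
        data = generate(sc, rng)
        data.metadata["fixture"] = name
        return data, {"alpha": sc.alpha, "phi": sc.phi, "beta": sc.beta}
    if name == "tvsfp_like_2x2":
        return _tvsfp_like(max(n, 1600), rng)
    if name == "likert5_feedback_like":
        sc = Scenario(
            case_id="fixture", label=name, true_family="stereotype",
            q=5, n=n,
            covariate_spec=[("normal", 0.0, 1.0), ("bernoulli", 0.5)],
            alpha=[0.0, -0.1, -0.8, -1.2, -1.6],
            phi=[0.0, 0.252, 0.748, 0.946, 1.0],
            beta=[1.0, 0.8],
        )
        data = generate(sc, rng)
        data.metadata["fixture"] = name
        return data, {"alpha": sc.alpha, "phi": sc.phi, "beta": sc.beta}
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
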