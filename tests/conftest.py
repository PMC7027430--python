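import numpy as np
import pytest

from ordstereo import OrdinalDataset, Scenario, gen_stereotype


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_q3_data():
    """n=200 dataset from a q=3 stereotype model with one normal and one
    binary covariate; small enough for fast fits."""
    sc = Scenario(
        case_id="test", label="small_q3", true_family="stereotype",
        q=3, n=200,
        covariate_spec=[("normal", 0.0, 1.0), ("bernoulli", 0.5)],
        alpha=[0.0, -0.6, -1.5], phi=[0.0, 0.5, 1.0], beta=[1.0, 1.5],
    )
    return gen_stereotype(sc, np.random.default_rng(7))


@pytest.fixture(scope="session")
def q4_data():
    """n=600 dataset from a q=4 stereotype model with uneven scores."""
    sc = Scenario(
        case_id="test", label="q4", true_family="stereotype",
        q=4, n=600,
        covariate_spec=[("normal", 0.0, 1.0), ("normal", 0.0, 1.0)],
        alpha=[0.0, 0.2, -0.8, -1.2], phi=[0.0, 0.2, 0.8, 1.0],
        beta=[0.8, -0.5],
    )
    return gen_stereotype(sc, np.random.default_rng(11))


@pytest.fixture(scope="session")
def binary_design_q4():
    """2x2 binary factorial design, q=4 — a categorical-pattern dataset."""
    sc = Scenario(
        case_id="test", label="2x2", true_family="stereotype",
        q=4, n=800,
        covariate_spec=[("bernoulli", 0.5), ("bernoulli", 0.5)],
        alpha=[0.0, 0.2, -0.3, -0.4], phi=[0.0, 0.3, 0.7, 1.0],
        beta=[0.9, 0.4],
    )
    return gen_stereotype(sc, np.random.default_rng(13))


@pytest.fixture()
def tiny_dataset():
    y = np.array([1, 2, 3, 1, 2, 3])
    X = np.array([[0.5], [-0.2], [1.1], [0.0], [0.3], [-0.7]])
    return OrdinalDataset(y=y, X=X, q=3)
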