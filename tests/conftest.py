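import numpy as np
import pytest

from ctdynet import CTModel, example_models, random_stable_drift


@pytest.fixture(scope="session")
def fixtures():
    return example_models()


@pytest.fixture(scope="session")
def stress_model(fixtures):
    return fixtures["stress_discomfort_partial"].model


@pytest.fixture(scope="session")
def chain3(fixtures):
    return fixtures["chain3"].model


@pytest.fixture(scope="session")
def negfeedback4(fixtures):
    return fixtures["negfeedback4"].model


def random_ct_models(n, p_values=(2, 3, 4, 5), seed0=100, diffusion="random"):
    """Deterministic battery of random stable CT models."""
    models = []
    rng = np.random.default_rng(seed0)
    for k in range(n):
        p = int(rng.choice(p_values))
        A = random_stable_drift(p, seed=seed0 + k)
        if diffusion == "random":
            L = np.tril(rng.normal(size=(p, p)))
            L[np.arange(p), np.arange(p)] = np.abs(L[np.arange(p), np.arange(p)]) + 0.3
            Q = L @ L.T
        else:
            Q = np.eye(p)
        models.append(CTModel(drift=A, diffusion=Q))
    return models


@pytest.fixture(scope="session")
def model_battery():
    return random_ct_models(20)
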