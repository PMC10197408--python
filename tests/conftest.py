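import numpy as np
import pandas as pd
import pytest

from healthineq import GeneratorConfig, generate_macro, generate_microdata


@pytest.fixture
def toy_sample():
    """Four persons, the two poorest with the outcome: the extreme pro-poor
    case with Erreygers index exactly -1."""
    return (np.array([1.0, 1.0, 0.0, 0.0]),   # h
            np.array([1.0, 2.0, 3.0, 4.0]),   # income
            np.ones(4))                        # weights


@pytest.fixture(scope="session")
def small_cohort():
    """Six-country rank-linear cohort reused across read-only tests."""
    cfg = GeneratorConfig(n_countries=6, persons_per_country=400, seed=12)
    return generate_microdata(cfg), generate_macro(cfg), cfg


def random_binary_sample(rng, n_max=200, allow_ties=True):
    n = int(rng.integers(4, n_max + 1))
    h = rng.integers(0, 2, n).astype(float)
    if allow_ties and rng.random() < 0.5:
        y = rng.integers(0, max(2, n // 3), n).astype(float)  # many ties
    else:
        y = rng.normal(size=n)
    w = rng.uniform(0.25, 4.0, n)
    return h, y, w
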