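import warnings

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # solver/recipe warnings are informational in tests unless asserted on
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_gaussian(rng):
    """n=60 standardized design with a sparse linear signal."""
    n, p = 60, 6
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.array([1.5, 0.0, -1.0, 0.0, 0.5, 0.0])
    y = X @ beta + 0.5 * rng.standard_normal(n)
    return X, y, beta


@pytest.fixture
def tiny_frame():
    """Small mixed-type frame for recipe tests."""
    rng = np.random.default_rng(7)
    n = 120
    return pd.DataFrame(
        {
            "age": rng.normal(50, 10, n),
            "dose": rng.normal(2, 1, n),
            "group": rng.choice(["A", "B", "C"], n, p=[0.5, 0.35, 0.15]),
            "flag": rng.integers(0, 2, n),
        }
    )
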