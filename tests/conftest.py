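import numpy as np
import pandas as pd
import pytest

import haisac


@pytest.fixture(scope="session")
def default_config():
    return haisac.default_config(seed=7)


@pytest.fixture(scope="session")
def factor_spec():
    return haisac.default_factor_spec()


@pytest.fixture(scope="session")
def item_cohort(default_config):
    """Default 761-subject item-level cohort (fixed seed)."""
    return haisac.simulate_item_cohort(default_config)


@pytest.fixture(scope="session")
def scored_battery(item_cohort):
    """Five-item scored battery (cnocd, ml, rfo, cd, fd) of the default cohort."""
    scored = haisac.score_items_frame(item_cohort)
    return scored[["cnocd", "ml", "rfo", "cd", "fd"]]


@pytest.fixture(scope="session")
def scale_cohort(default_config):
    """Default untruncated scale-level cohort (fixed seed)."""
    return haisac.simulate_scale_cohort(default_config)


def make_data_with_exact_corr(R: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an n × p sample whose *sample* correlation matrix equals R exactly.

    Whitens an arbitrary Gaussian draw with its own empirical covariance and
    re-colors it with R^(1/2); used to test statistics whose value is a pure
    function of the sample correlation matrix.
    """
    p = R.shape[0]
    X = rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    w, V = np.linalg.eigh(cov)
    whiten = V @ np.diag(w**-0.5) @ V.T
    w2, V2 = np.linalg.eigh(R)
    color = V2 @ np.diag(np.sqrt(np.clip(w2, 0, None))) @ V2.T
    return X @ whiten @ color
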