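import numpy as np
import pandas as pd
import pytest

import codaprop as cp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_matrix():
    """A 300 x 10 survey-like composition matrix, seeded."""
    return cp.gemas_like_fixture(seed=11, scale="small")


@pytest.fixture
def toy_matrix():
    return pd.DataFrame(
        [[1.0, 2.0, 4.0],
         [2.0, 2.0, 2.0],
         [4.0, 1.0, 1.0],
         [3.0, 5.0, 2.0]],
        columns=["a", "b", "c"])


def random_composition(rng, D):
    """A random strictly positive D-part vector with spread log-scales."""
    return np.exp(rng.normal(scale=1.5, size=D))


def family_z_bound(m: int) -> float:
    """Per-comparison z threshold for m simultaneous checks whose family
    false-alarm rate equals a single two-sided three-sigma test (0.27%)."""
    from scipy import stats
    return float(stats.norm.ppf(1 - 0.0027 / (2 * m)))


def check_moment_recovery(Z, mean, cov):
    """Assert empirical ilr mean/cov of Z recover (mean, cov) within a
    family-calibrated three-sigma band."""
    n, p = Z.shape
    z_mean = (Z.mean(axis=0) - mean) / np.sqrt(np.diag(cov) / n)
    S = np.cov(Z, rowvar=False, ddof=1)
    se_cov = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / (n - 1))
    z_cov = (S - cov) / se_cov
    iu = np.triu_indices(p)
    m = p + len(iu[0])
    bound = family_z_bound(m)
    assert np.abs(z_mean).max() < bound
    assert np.abs(z_cov[iu]).max() < bound
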