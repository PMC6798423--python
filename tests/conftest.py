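import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sda.core import DesignMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def two_group_design(n0: int, n1: int) -> DesignMatrix:
    """Binary group design: first n0 samples are group 0."""
    x = np.array([0.0] * n0 + [1.0] * n1)[:, None]
    return DesignMatrix(X=x, test_index=0)


@pytest.fixture
def design_50_50():
    return two_group_design(50, 50)


def grid_search_beta(logy, x, h, lo=-2.0, hi=2.0, step=1e-4):
    """Independent grid-search oracle for the 1-covariate smoothed likelihood."""
    grid = np.arange(lo, hi + step, step)
    best_b, best_ll = None, -np.inf
    for chunk in np.array_split(grid, 40):
        r = logy[None, :] - chunk[:, None] * x[:, 0][None, :]
        d = (r[:, None, :] - r[:, :, None]) / h
        k = np.exp(-0.5 * d * d)
        ll = np.log(k.sum(axis=2)).sum(axis=1)
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best_b = float(ll[i]), float(chunk[i])
    return best_b


def null_two_group_feature(rng, n=50, p_zero=0.3, source=None, censor=False,
                           censor_q=0.10):
    """One feature with identical distributions in both groups."""
    from sda.simulate import skewed_source

    source = source or skewed_source
    N = 2 * n
    vals = np.zeros(N)
    keep = rng.random(N) >= p_zero
    vals[keep] = np.exp(source(rng, int(keep.sum())))
    if censor:
        nz = vals[vals > 0]
        if nz.size:
            limit = np.quantile(nz, censor_q)
            vals[vals < limit] = 0.0
    return vals
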