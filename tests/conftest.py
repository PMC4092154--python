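import numpy as np
import pandas as pd
import pytest

from zicpue.simulate import default_scenario


@pytest.fixture(scope="session")
def survey():
    """One realized default synthetic survey (cheap, reused read-only)."""
    return default_scenario(3)


@pytest.fixture
def zip_frame():
    """Factory for simple zero-inflated Poisson data with one covariate.

    log mu = log(hooks) + baseline + f(x); logit p = zero_eta(x).
    """

    def make(
        n=800,
        seed=0,
        baseline=-6.0,
        f=np.sin,
        p_fun=lambda x: np.full_like(x, 0.3),
        hooks=400.0,
        x_range=(0.0, 10.0),
    ):
        rng = np.random.default_rng(seed)
        x = rng.uniform(*x_range, n)
        h = np.full(n, float(hooks))
        mu = np.exp(np.log(h) + baseline + f(x))
        p = p_fun(x)
        y = np.where(rng.random(n) < p, rng.poisson(mu), 0)
        return pd.DataFrame({"x": x, "effort_hooks": h, "y": y}), mu, p

    return make
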