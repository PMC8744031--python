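import numpy as np
import pytest

import lifeineq as li


@pytest.fixture(scope="session")
def fx():
    """Named analytic fixture constructors."""
    return li.fixtures()


@pytest.fixture(scope="session")
def uniform10(fx):
    """Equal point masses on ages 0..9 (AID = 1.65, G = 11/30 by brute force)."""
    return fx["uniform"](10)


@pytest.fixture(scope="session")
def siler_pair():
    """High- and low-mortality Siler life tables bracketing the transition."""
    lt1 = li.siler_lifetable(li.SILER_HIGH_MORTALITY, year=1850)
    lt2 = li.siler_lifetable(li.SILER_LOW_MORTALITY, year=2015)
    return lt1, lt2


@pytest.fixture(scope="session")
def transition_panel():
    """Deterministic 40-year, 3-population synthetic panel."""
    return li.generate_transition_panel(years=40, populations=3, seed=11)


def random_distribution(rng, n_max=40, omega=122.0):
    """A random discrete age-at-death distribution with support in [0, omega]."""
    n = rng.integers(2, n_max)
    xbar = np.sort(rng.uniform(0.0, omega, size=n))
    w = rng.dirichlet(np.ones(n) * rng.uniform(0.2, 3.0))
    return li.from_counts(xbar, w, xbar=xbar)
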