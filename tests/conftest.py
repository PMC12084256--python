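import numpy as np
import pytest

from qssa.kinetics import RateConstants


def draw_params(rng: np.random.Generator, n: int,
                k_range=(1e-2, 1e2), e0_range=(1e-3, 1e2)) -> list[RateConstants]:
    """Log-uniform random parameter sets with all rates strictly positive."""
    lo, hi = np.log(k_range[0]), np.log(k_range[1])
    ks = np.exp(rng.uniform(lo, hi, size=(n, 3)))
    e0 = np.exp(rng.uniform(np.log(e0_range[0]), np.log(e0_range[1]), size=n))
    return [RateConstants(k1=row[0], k_neg1=row[1], k2=row[2], e0=e)
            for row, e in zip(ks, e0)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def param_draws(rng):
    """1000 random parameter sets shared by the identity property tests."""
    return draw_params(np.random.default_rng(7), 1000)


@pytest.fixture
def unit_params():
    """k1 = k_neg1 = k2 = 1, e0 = 6: the phase-plane workhorse parameter set."""
    return RateConstants(k1=1.0, k_neg1=1.0, k2=1.0, e0=6.0)
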