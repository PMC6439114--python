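import numpy as np
import pytest
from hypothesis import strategies as st

from mitolineage import make_empirical_pmf, parametric_pmf, synth_census_like


@pytest.fixture(scope="session")
def zero_law():
    """Founder never has daughters: extinct at generation 1, always."""
    return make_empirical_pmf([0], [1], label="zero")


@pytest.fixture(scope="session")
def unit_law():
    """Exactly one daughter per woman: the immortal single-file lineage."""
    return make_empirical_pmf([1], [2], label="unit")


@pytest.fixture(scope="session")
def binary_fission():
    """0 or 2 daughters (0.2 / 0.8): supercritical with q* = 1/4 exactly."""
    return make_empirical_pmf([0, 2], [1, 4], label="binary-fission")


@pytest.fixture(scope="session")
def critical_geometric():
    """P(k) = 0.5^(k+1) truncated far into the tail; mean 1, q_n = n/(n+1)."""
    k = np.arange(201)
    return make_empirical_pmf(k, 0.5 ** (k + 1.0), label="critical-geometric")


@pytest.fixture(scope="session")
def poisson_half():
    return parametric_pmf("poisson", 0.5)


@pytest.fixture(scope="session")
def poisson_095():
    return parametric_pmf("poisson", 0.95)


@pytest.fixture(scope="session")
def census_standin():
    """Default synthetic census-like daughter law (mean 0.95, seed 1)."""
    return synth_census_like(seed=1)


def pmf_strategy(max_count: int = 8, min_size: int = 1):
    """Hypothesis strategy for random valid offspring PMFs."""
    return (
        st.dictionaries(
            st.integers(min_value=0, max_value=max_count),
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=min_size,
            max_size=max_count + 1,
        )
        .filter(lambda d: sum(d.values()) > 1e-6)
        .map(
            lambda d: make_empirical_pmf(
                list(d.keys()), list(d.values()), label="hypothesis"
            )
        )
    )
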