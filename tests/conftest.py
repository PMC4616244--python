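import pytest

from gridcode import optimize_prob


@pytest.fixture(scope="session")
def opt1d():
    """1D probabilistic-decoder optimum (shared: the optimization is costly)."""
    return optimize_prob(1)


@pytest.fixture(scope="session")
def opt2d_free():
    """2D probabilistic optimum with free lattice geometry."""
    return optimize_prob(2, geometry_mode="free")


@pytest.fixture(scope="session")
def opt2d_tri():
    """2D probabilistic optimum at the fixed triangular lattice."""
    return optimize_prob(2, geometry_mode="triangular")
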