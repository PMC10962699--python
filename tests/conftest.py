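import numpy as np
import pytest

from rsakit import (
    build_default_design,
    make_shape_model_rdm,
    make_type_model_rdm,
)


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def type_rdm(design):
    return make_type_model_rdm(design)


@pytest.fixture(scope="session")
def shape_rdm(design):
    return make_shape_model_rdm(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_symmetric_rdm(rng, n, tie_free=False):
    """A random valid RDM on n items; tie_free draws distinct off-diagonal values."""
    from rsakit import RDM

    m = n * (n - 1) // 2
    if tie_free:
        vals = rng.permutation(np.linspace(0.1, 1.0, m))
    else:
        vals = rng.random(m)
    return RDM.from_lower_triangle(vals, [f"s{i}" for i in range(n)])
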