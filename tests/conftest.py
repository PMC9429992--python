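import numpy as np
import pytest

from angioseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 40-cube phantom (scan, GT, centerlines)."""
    spec = PhantomSpec(shape=(40, 40, 40), n_trees=2,
                       radius_range=(1.2, 2.5), seed=7)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
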