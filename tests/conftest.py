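import numpy as np
import pytest

from dcanet.phantoms import PhantomSpec, generate_phantom, _child_seed


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=42)


def make_samples(spec: PhantomSpec, n: int, base_seed: int):
    """Generate n phantoms with deterministic per-item seeds."""
    return [generate_phantom(spec.replace(seed=_child_seed(base_seed, i)))
            for i in range(n)]


@pytest.fixture(scope="session")
def small_samples(default_spec):
    """A small phantom batch reused by fast tests."""
    return make_samples(default_spec, 12, base_seed=42)
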