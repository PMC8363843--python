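import pytest
from hypothesis import settings

from genophen_store import SMALL, Store
from genophen_store.fixtures import FixtureSpec, seed_store

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: small-but-not-trivial spec for tests that mutate their own store
TINY = FixtureSpec(
    seed=7, n_backbones=2, backbone_length=400,
    n_variants=8, n_samples=4,
    n_traits=2, n_siteyears=2, n_reps=2, n_germplasm=5,
    quantitative_fraction=0.5,
)


@pytest.fixture
def store():
    return Store()


@pytest.fixture(scope="session")
def seeded():
    """Small-preset store seeded end-to-end, with its manifests.

    Session-scoped; tests treat it as read-only and build their own store
    when they need to mutate.
    """
    st = Store()
    result = seed_store(st, SMALL)
    return st, result


@pytest.fixture
def tiny_store():
    st = Store()
    result = seed_store(st, TINY)
    return st, result
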