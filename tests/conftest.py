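import pytest

import starallele as sa
from starallele.simulate import make_reference


@pytest.fixture(scope="session")
def toy_db():
    return sa.bundled_database("toy_gene")


@pytest.fixture(scope="session")
def demo_db():
    return sa.bundled_database("cyp2d6_demo")


@pytest.fixture(scope="session")
def demo_ref(demo_db):
    """Noiseless uniform-technology reference for the demo cluster."""
    return make_reference(demo_db, depth=30.0, bias="uniform", seed=1, noise=False)


@pytest.fixture(scope="session")
def toy_ref(toy_db):
    return make_reference(toy_db, depth=40.0, bias="uniform", seed=1, noise=False)
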