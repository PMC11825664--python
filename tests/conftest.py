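import numpy as np
import pytest

from normeval import generate_bundle, make_toy_backends, stub_restorer


@pytest.fixture(scope="session")
def toy_backends():
    return make_toy_backends(seed=0)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small fixed-seed bundle shared by read-only tests."""
    return generate_bundle(seed=11, n_healthy=8, n_unseen=4, n_path=6)


@pytest.fixture(scope="session")
def restored_bundles(tiny_bundle):
    bundle, _ = tiny_bundle
    return {
        kind: stub_restorer(kind, bundle)
        for kind in ("identity", "oracle", "blur")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
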