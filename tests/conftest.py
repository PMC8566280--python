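import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Small phantom shared by read-only tests (32×32×12, 8 volumes)."""
    from dstripe.simulate import PhantomConfig, make_phantom

    cfg = PhantomConfig(shape=(32, 32, 12), volumes_per_shell=(2, 3, 3))
    return make_phantom(cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def tiny_net():
    """An untrained network with deterministic weights (shared, read-only)."""
    from dstripe.network import DStripeNet

    return DStripeNet(seed=42)
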