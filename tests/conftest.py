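import numpy as np
import pytest

from floodmig import WorldConfig, generate_world


@pytest.fixture(scope="session")
def desk_world():
    """Default 20-district desk-scale world (session-shared, reset per use)."""
    return generate_world(WorldConfig.desk(), seed=1)


@pytest.fixture()
def tiny_world():
    """3-district world with few layers, for brute-force comparisons."""
    config = WorldConfig(
        n_districts=3,
        n_coastal=1,
        extent=4.0,
        coastal_layers=(2, 3),
        interior_layers=(2, 3),
    )
    return generate_world(config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
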