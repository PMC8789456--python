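import numpy as np
import pytest

from hemofuse.synthetic import SyntheticConfig, generate_dataset, skull_geometry


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    """Six clean samples per subtype; shared across segmentation tests."""
    cfg = SyntheticConfig(
        counts={c: 6 for c in ("EPI", "IVT", "IPC", "SBD", "SAD")},
        gaussian_sigma=0.0,
        salt_pepper_rate=0.0,
        seed=0,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def geometry():
    return skull_geometry(64)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
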