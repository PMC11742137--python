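import numpy as np
import pytest

from metalmap import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def fixture7():
    """One fully generated synthetic section pair, shared across tests."""
    return make_fixture(FixtureSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_elemental_map(rng, n_channels=4, shape=(12, 15), missing_frac=0.1):
    """Small random map with scattered missing pixels, for oracle tests."""
    from metalmap import ElementalMap

    data = rng.gamma(2.0, 2.0, size=(n_channels, *shape))
    data[rng.random(data.shape) < 0.25] = 0.0
    missing = rng.random(data.shape) < missing_frac
    data = np.where(missing, np.nan, data)
    return ElementalMap(
        data=data,
        channel_names=[f"El{i}" for i in range(n_channels)],
        pixel_size_um=5.0,
        missing_mask=missing,
        frame_id="elemental",
    )
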