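import numpy as np
import pytest

import periopix as pp


@pytest.fixture(scope="session")
def scene_bank():
    """260 synthetic scenes at the default study ranges, rendered once."""
    return pp.make_dataset(260, 42)


@pytest.fixture(scope="session")
def one_scene():
    return pp.render_scene(pp.sample_scene_params(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
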