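import numpy as np
import pytest

from retroscreen import synthetic as syn


@pytest.fixture(scope="session")
def toy_complex():
    return syn.make_toy_complex()


@pytest.fixture(scope="session")
def default_config():
    return syn.SyntheticConfig(seed=12345)


@pytest.fixture(scope="session")
def synthetic_screen(default_config):
    """Library + truth + pose-score table under the default study conditions."""
    library, truth = syn.gen_library(default_config)
    table = syn.gen_pose_scores(default_config, library, truth)
    return default_config, library, truth, table


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
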