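import numpy as np
import pytest

from cooptom.agents import ALTRUISTIC, BR, SELFISH
from cooptom.game_generator import GeneratorParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pair_params():
    """Two-player-only sampling, no observation noise."""
    return GeneratorParams(player_counts={2: 1.0})


@pytest.fixture
def utility_roster():
    return (BR, SELFISH, ALTRUISTIC)
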