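import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message="ArviZ is undergoing")

from datedelay.geometry import ScreenGeometry, build_block_plan, make_default_aois
from datedelay.simulate import draw_participants, generate_item_bank, simulate_choices


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def aois(geometry):
    return make_default_aois(geometry)


@pytest.fixture(scope="session")
def item_bank():
    return generate_item_bank(seed=11)


@pytest.fixture(scope="session")
def block_plan():
    return build_block_plan(27, "delay", seed=11)


@pytest.fixture(scope="session")
def small_choices(item_bank, block_plan):
    """Choice tables for a handful of participants (fast fits)."""
    import pandas as pd
    parts = draw_participants(8, seed=21)
    frames = [simulate_choices(p, item_bank, block_plan, seed=50 + i)
              for i, p in enumerate(parts)]
    return pd.concat(frames, ignore_index=True), parts
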