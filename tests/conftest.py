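import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # makes `oracles` importable

import ccrit as cc


@pytest.fixture
def rng():
    return np.random.default_rng(20170901)


@pytest.fixture(scope="session")
def small_specimen():
    """A compact 4-ommatidium specimen with 20 spots per expressing cell,
    shared by tests that only need a realistic rendered pair of stacks."""
    truth = cc.generate_layout(n_ommatidia=4, ring_radius=28, spacing=88,
                               shape=(288, 288), n_slices=6,
                               nucleus_radius=8, seed=42)
    cc.plant_spots(truth, spots_per_cell=20, seed=43)
    nucleus, fish = cc.render_stacks(truth, seed=44)
    return truth, nucleus, fish


@pytest.fixture(scope="session")
def small_result(small_specimen):
    truth, nucleus, fish = small_specimen
    return truth, cc.run_ccrit(nucleus, fish)
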