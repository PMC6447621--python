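import numpy as np
import pytest

import triplet_mmn as tm
from triplet_mmn.simulate import NoiseSpec


@pytest.fixture(scope="session")
def design():
    return tm.make_design(participant_id=1, master_seed=7)


@pytest.fixture(scope="session")
def block(design):
    """One default 400-triplet block."""
    return tm.generate_block(design, 0)


@pytest.fixture(scope="session")
def block_with_targets(design, block):
    return tm.insert_targets(block, design)


@pytest.fixture(scope="session")
def soundbank(design):
    return tm.build_soundbank(design)


@pytest.fixture(scope="session")
def montage():
    return tm.standard_montage()


@pytest.fixture(scope="session")
def short_design():
    """A small 100-triplet design for fast simulation tests."""
    return tm.make_design(participant_id=2, master_seed=11, triplets_per_block=100,
                          target_rate=2)


@pytest.fixture(scope="session")
def short_block(short_design):
    """Short block including the cover-task target events."""
    return tm.insert_targets(tm.generate_block(short_design, 0), short_design)


@pytest.fixture(scope="session")
def silent_recording(short_design, short_block):
    """Noiseless simulation of a short block (ground-truth oracle substrate)."""
    return tm.simulate_block(
        short_design, short_block, noise_spec=NoiseSpec().silent(), seed=3
    )


@pytest.fixture(scope="session")
def noisy_recording(short_design, short_block):
    return tm.simulate_block(short_design, short_block, seed=4)
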