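import numpy as np
import pandas as pd
import pytest

import cortflow as cf


@pytest.fixture(scope="session")
def geometry60():
    return cf.generate_geometry(60, seed=42)


@pytest.fixture(scope="session")
def ground_truth_small():
    """60 parcels, 4 conditions: enough structure for module-level checks."""
    return cf.generate_ground_truth(60, 4, seed=7)


@pytest.fixture(scope="session")
def design_small():
    return cf.generate_block_design(
        n_conditions=4, blocks_per_condition=3, block_len_s=10.0, rest_len_s=10.0, tr_s=0.72
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_design(blocks, tr_s=1.0, n_tr=None):
    """Design from (onset, duration, label) triples."""
    ev = pd.DataFrame(blocks, columns=["onset", "duration", "trial_type"])
    if n_tr is None:
        n_tr = int(np.ceil((ev["onset"] + ev["duration"]).max() / tr_s)) + 5
    return cf.TaskDesign(ev, tr_s, n_tr)
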