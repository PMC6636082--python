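import numpy as np
import pytest

import speechtrack as st
from speechtrack import synthetic


@pytest.fixture(scope="session")
def grid():
    return st.design_grid()


@pytest.fixture(scope="session")
def small_synth(grid):
    """A small deterministic synthetic dataset shared across test modules.

    60 s per condition, 3 channels, default-latency ground
    truth, moderate 1/f noise.
    """
    gt = synthetic.default_ground_truth(3, seed=11)
    envs = synthetic.synth_condition_envelopes(grid, 60.0, seed=12)
    eegs = synthetic.synth_eeg(grid, envs, gt, noise_gain=1.0, seed=13)
    return dict(gt=gt, envs=envs, eegs=eegs)


@pytest.fixture(scope="session")
def small_conditions(grid, small_synth):
    """(features, eeg) condition list for the encoding model."""
    conds = []
    for row, label in zip(grid, grid.labels):
        y_t, y_b = small_synth["envs"][label]
        feats = st.build_features(y_t, y_b, row.clarity_pct / 100.0,
                                  row.comprehension_pct / 100.0)
        conds.append((feats, small_synth["eegs"][label]))
    return conds
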