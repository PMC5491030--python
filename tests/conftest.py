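import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import milieu

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One default-design synthetic study (n = 211, four groups), with all
    derived objects, shared across tests."""
    raw, truth = milieu.generate_dataset(milieu.default_study_config(), seed=0)
    std = milieu.standardize(raw)
    blocks = milieu.assemble_blocks(std)
    return {"raw": raw, "truth": truth, "std": std, "blocks": blocks,
            "y": std.health_index.to_numpy()}


@pytest.fixture(scope="session")
def fast_net():
    """Reduced training budget for tests that fit many networks."""
    return milieu.MLPWaveRegressor(restarts=2, max_epochs=400, patience=25)


def make_blocks(rng, n, widths=(4, 3, 5, 4, 3)):
    """Small synthetic PredictorBlocks with standard-normal columns."""
    names = milieu.data.BLOCK_NAMES
    frames = {}
    for name, w in zip(names, widths):
        cols = [f"{name[:4]}_{j}" for j in range(w)]
        frames[name] = pd.DataFrame(rng.standard_normal((n, w)), columns=cols)
    return milieu.PredictorBlocks(frames)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
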