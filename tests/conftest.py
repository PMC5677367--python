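import numpy as np
import pandas as pd
import pytest

from avapipe import simnet
from avapipe.raster import ArrayGeometry, EventRaster


@pytest.fixture(scope="session")
def critical_sizes():
    """Sizes of 30k cascades from the critical 10x10 network (session cache)."""
    sizes, _ = simnet.run_avalanches(simnet.SimConfig(rng_seed=101), 30000)
    return sizes


@pytest.fixture(scope="session")
def baseline_log():
    """A modest baseline event log with ground-truth labels."""
    return simnet.run_baseline(simnet.SimConfig(rng_seed=202), 2000)


def make_raster(events, trial_span=None, n_electrodes=96):
    df = pd.DataFrame(events, columns=["electrode", "trial", "time"])
    df["amplitude"] = 0.0
    return EventRaster(df, ArrayGeometry(n_electrodes=n_electrodes), trial_span)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
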