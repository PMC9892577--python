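import numpy as np
import pandas as pd
import pytest

from exotrace.models import (
    BindingModel,
    DegradationModel,
    TraceConfig,
    default_nucleoside_table,
)

HET_30MER = "CGAUCUUCAUUGCCAAGCGGCUAGCUCAAA"
MCCA_24MER = "UACGCAUGACCAUUACGUUUGAUU"


@pytest.fixture(scope="session")
def nk():
    return default_nucleoside_table()


@pytest.fixture(scope="session")
def dm():
    return DegradationModel()


@pytest.fixture(scope="session")
def binding():
    return BindingModel()


@pytest.fixture
def fast_config():
    """7200 Sa/s acquisition for quick session-scale tests."""
    return TraceConfig(sampling_rate=7200.0, noise_sd=0.15, seed=0)


def make_events(states, dwells, currents=None, fs=1.0):
    """Hand-built event table for segmentation/statistics tests."""
    starts = np.concatenate(([0.0], np.cumsum(dwells)[:-1]))
    if currents is None:
        currents = [{"low": 1.0, "mid": 2.0, "high": 3.0}[s] for s in states]
    return pd.DataFrame({"state": states, "start_s": starts,
                         "dwell_s": dwells, "mean_current_nA": currents})
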