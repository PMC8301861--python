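import warnings

import numpy as np
import pytest

from plrkit import PupilTrace, StimulusSpec, simulate_plr, staged_fit
from plrkit.reference import duration_study_table, default_search_space

STIM_ONSET = 5.0
RATE = 30.0


@pytest.fixture(scope="session")
def time_grid():
    return np.arange(0.0, 15.0 + 0.5 / RATE, 1.0 / RATE)


@pytest.fixture(scope="session")
def reference_table():
    return duration_study_table()


@pytest.fixture(scope="session")
def search_space():
    return default_search_space()


@pytest.fixture(scope="session")
def reference_traces(reference_table, time_grid):
    """Noiseless simulations of the bundled parameter sets, one per duration."""
    out = {}
    for d, p in zip(reference_table.durations, reference_table.params):
        out[d] = simulate_plr(p, StimulusSpec(STIM_ONSET, d), time_grid)
    return out


@pytest.fixture(scope="session")
def noiseless_fits(reference_traces):
    """Staged fits of the noiseless reference traces (shared: they are slow)."""
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d, trace in reference_traces.items():
            fits[d] = staged_fit(trace, StimulusSpec(STIM_ONSET, d))
    return fits
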