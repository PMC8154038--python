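import numpy as np
import pytest

import mgcpn
from mgcpn.analysis import session_mzifr


@pytest.fixture(scope="session")
def default_session():
    """A small default-population recording session (5 trials/stimulus)."""
    return mgcpn.simulate_recording_session(trials_per_stimulus=5, seed=11)


@pytest.fixture(scope="session")
def default_traces(default_session):
    return session_mzifr(default_session)


@pytest.fixture(scope="session")
def calcium_study():
    """Default 8-individual calcium study."""
    return mgcpn.simulate_calcium_study(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
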