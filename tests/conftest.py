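import numpy as np
import pytest

import boutometry as bm


@pytest.fixture(scope="session")
def config_short() -> bm.SessionConfig:
    """A 10-minute variable-palatability session (five 2-min blocks)."""
    return bm.SessionConfig(session_length_s=600.0, seed=11)


@pytest.fixture(scope="session")
def params_default() -> bm.SimParams:
    return bm.SimParams(seed=11)


@pytest.fixture(scope="session")
def bundle(config_short, params_default) -> bm.SessionBundle:
    return bm.simulate_session(config_short, params_default)


@pytest.fixture(scope="session")
def processed_trace(bundle) -> bm.PhotometryTrace:
    return bm.preprocess(bundle.trace, bundle.session, mode="chunked")


def make_session(times, config=None, session_length=None, spouts=None):
    """Build a LickSession from bare lick times (helper for hand examples)."""
    times = np.asarray(times, dtype=float)
    if config is None:
        if session_length is None:
            last = times[-1] if times.size else 0.0
            session_length = 120.0 * max(1, int(np.ceil((last + 1.0) / 120.0)))
        config = bm.SessionConfig(session_length_s=session_length)
    if spouts is None:
        spouts = np.full(times.shape, "A", dtype=object)
    return bm.LickSession(times, spouts, config)
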