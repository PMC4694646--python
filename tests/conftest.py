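import numpy as np
import pytest

import connvar as cv
from connvar.core import STATE_BANDPASSED, STATE_CLEANED, SessionTimeSeries


@pytest.fixture(scope="session")
def ico1():
    return cv.build_icosphere(1)          # 42 vertices


@pytest.fixture(scope="session")
def ico2():
    return cv.build_icosphere(2)          # 162 vertices


@pytest.fixture(scope="session")
def atlas2(ico2):
    return cv.assign_networks(ico2, n_labels=7, seed=7)


@pytest.fixture(scope="session")
def small_cohort(ico1):
    """6 subjects x 4 sessions on the 42-vertex mesh; cheap but balanced."""
    atlas = cv.assign_networks(ico1, n_labels=3, seed=3)
    config = cv.CohortConfig(n_subjects=6, n_sessions=4, t_raw=120,
                             seed=2024)
    return cv.simulate_cohort(ico1, atlas, config)


def make_session(data, dt=2.0, state=STATE_CLEANED, **kw):
    return SessionTimeSeries(data=np.asarray(data, dtype=float), dt=dt,
                             subject_id="subX", session_id="sesX",
                             state=state, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cleaned_session(rng):
    return make_session(rng.standard_normal((30, 120)))


@pytest.fixture
def bandpassed_session(rng):
    ts = make_session(rng.standard_normal((30, 120)))
    return cv.bandpass(ts, 0.01, 0.1)
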