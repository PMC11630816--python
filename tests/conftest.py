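import numpy as np
import pytest

from usv44.calltable_io import CallContour, CallRecord, SessionMeta
from usv44.simulate import SyntheticConfig, generate_cohort


def make_record(
    call_id="c0",
    onset=0.0,
    duration=0.5,
    peak_frequency=25_000.0,
    rat_id="r1",
    session_id="s1",
    **kwargs,
):
    return CallRecord(
        call_id=call_id,
        rat_id=rat_id,
        session_id=session_id,
        onset=onset,
        duration=duration,
        peak_frequency=peak_frequency,
        **kwargs,
    )


def flat_contour(frequency, duration=0.5, n=50, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n)
    f = np.full(n, float(frequency))
    if jitter:
        f = f + rng.uniform(-jitter, jitter, n)
    return CallContour(times=t, frequencies=f)


@pytest.fixture(scope="session")
def small_cohort():
    """4 rats, fixed seed; used by recovery-style unit tests."""
    return generate_cohort(SyntheticConfig(n_rats=4), seed=1)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (8 rats), fixed seed."""
    return generate_cohort(SyntheticConfig(), seed=7)


@pytest.fixture
def simple_meta():
    return SessionMeta(
        rat_id="r1",
        session_id="s1",
        shock_times=(60.0, 120.0),
        session_length=200.0,
        frame_rate=30.0,
    )
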