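import numpy as np
import pytest

from docmark.io import EventSchedule, ScrTrace, VolumeMap


@pytest.fixture
def simple_trace():
    """60 s of flat 2.0 uS at 50 Hz."""
    return ScrTrace(samples=np.full(3001, 2.0), rate=50.0)


@pytest.fixture
def two_event_schedule():
    return EventSchedule(onsets=np.array([10.0, 22.0]),
                         conditions=np.array(["word", "pseudoword"], dtype=object))


def make_random_trace(seed, n=30000, rate=500.0):
    rng = np.random.default_rng(seed)
    return ScrTrace(samples=2.0 + np.cumsum(rng.normal(0, 1e-3, n)) + rng.normal(0, 0.02, n),
                    rate=rate)


@pytest.fixture
def identity_affine():
    return np.eye(4)


def make_volume(data, affine=None, mask=None):
    return VolumeMap(data=np.asarray(data, dtype=float),
                     affine=np.eye(4) if affine is None else affine,
                     mask=mask)
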