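import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrvgaps.windows import Window5

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_window(offsets_s, ibis, start=0):
    """Build a Window5 from beat offsets (seconds from window start)."""
    offsets_s = np.asarray(offsets_s, dtype=float)
    return Window5(start=start,
                   timestamps=(start + offsets_s * 1000).astype(np.int64),
                   ibi=np.asarray(ibis, dtype=float))


def one_hz_window(start=0, n=300, ibi=1000.0):
    """A gap-free window with one beat per second."""
    return make_window(np.arange(n), np.full(n, ibi), start=start)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
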