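import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dosewalk as dw

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def curves():
    """The three study dose-response curves, keyed by id."""
    return {cid: dw.build_curve(cid) for cid in (1, 2, 3)}


@pytest.fixture(scope="session")
def true_ed95(curves):
    return {cid: dw.find_ed(c, 0.95) for cid, c in curves.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20230927)


class QueuedRng:
    """Deterministic stand-in for a Generator, yielding queued uniforms."""

    def __init__(self, values):
        self._values = list(values)

    def random(self, size=None):
        if size is None:
            return self._values.pop(0)
        out = np.array([self._values.pop(0) for _ in range(size)])
        return out


@pytest.fixture()
def queued_rng():
    return QueuedRng
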