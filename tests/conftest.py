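import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_moving_average(x, window):
    """Reference truncated-window centered moving average (O(n*w))."""
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def naive_kz(x, window, iterations):
    for _ in range(iterations):
        x = naive_moving_average(x, window)
    return x
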