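import numpy as np
import pytest

from s2map import SignalMatrix, SignalSeries, SimulationSpec2D, simulate_series


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def translation_spec():
    return SimulationSpec2D(model="translation")


@pytest.fixture
def circular_series() -> SignalSeries:
    return simulate_series(SimulationSpec2D(model="circular_propagation"))


@pytest.fixture
def small_series(rng) -> SignalSeries:
    """A 9x9, five-frame synthetic secretion series with growing signal."""
    frames = []
    base = rng.random((9, 9))
    for t in range(5):
        bump = np.zeros((9, 9))
        bump[4, 4 + min(t, 4) // 2] = 10.0 * t
        frames.append(SignalMatrix(base + bump))
    return SignalSeries(frames, times=np.arange(5, dtype=float), sample_id="synthetic")


def brute_force_di(x) -> float:
    """Independent Lorenz-curve oracle: explicit loop over prefix shares."""
    x = [float(v) for v in x]
    n = len(x)
    total = sum(x)
    if total == 0:
        return 0.0
    acc = 0.0
    running = 0.0
    for k in range(1, n + 1):
        running += x[k - 1]
        acc += 2.0 * (running / total - k / n)
    return acc / n
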