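import numpy as np
import pytest
from hypothesis import settings

import icptools as it

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_truth() -> it.SynthTruth:
    """One default-regime synthetic recording, shared read-only."""
    return it.generate_recording(it.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_pipeline(default_truth):
    return it.IcpEventClassifier().fit(default_truth.recording)


@pytest.fixture()
def small_recording() -> it.Recording:
    rng = np.random.default_rng(0)
    traces = 1.0 + 0.01 * rng.standard_normal((4, 40))
    return it.Recording(traces, [f"c{i}" for i in range(4)], sample_period_s=3.0)


def brute_extrema(x):
    """Independent neighbor-scan oracle: interior extrema, plateaus
    collapsed to their leftmost sample, boundaries never extrema."""
    x = list(x)
    n = len(x)
    maxima, minima = [], []
    for i in range(1, n - 1):
        if x[i] == x[i - 1]:
            continue  # not the leftmost sample of its plateau
        j = i
        while j + 1 < n and x[j + 1] == x[j]:
            j += 1
        if j == n - 1:
            continue  # plateau reaches the right boundary
        left, right = x[i - 1], x[j + 1]
        if left < x[i] and x[i] > right:
            maxima.append(i)
        if left > x[i] and x[i] < right:
            minima.append(i)
    return maxima, minima


def brute_pairs(x, maxima, minima):
    """Oracle pairing: every maximum with its closest left minimum."""
    out = []
    for m in maxima:
        left = [mn for mn in minima if mn < m]
        if left:
            lm = max(left)
            out.append((lm, m, x[m] - x[lm]))
    return out
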