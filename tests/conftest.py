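import numpy as np
import pytest

from survformer import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small dual-signal cohort shared by pipeline-level tests."""
    return simulate_cohort(SimConfig(n=100, p=(12, 10), seed=7))


def random_survival(rng, n, censor_frac=0.3, tie_frac=0.0):
    """Random right-censored survival data for metric oracles."""
    time = rng.exponential(scale=10.0, size=n)
    if tie_frac > 0:
        time = np.round(time, 0) + 1.0  # induce ties, keep positivity
    event = (rng.random(n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[int(rng.integers(n))] = 1
    return time, event
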