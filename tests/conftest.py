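import numpy as np
import pytest

from occupeak.intervals import GenomicInterval, IntervalCollection
from occupeak.simulate import SimulationConfig, simulate_cohort


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_coord=100_000, max_len=2_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_coord - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return IntervalCollection(out)


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast module tests (same design, fewer sites)."""
    return SimulationConfig(seed=11, n_sites=120, n_chroms=2, n_transcripts=80)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
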