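import numpy as np
import pytest

from dockscan.intervals import GenomicInterval, Peak
from dockscan.simulate import SimulationConfig, generate_genome


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def peak(chrom, start, end, signal=1.0, name="."):
    return Peak(GenomicInterval(chrom, start, end),
                summit=(start + end) // 2, signal=signal, name=name)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + int(rng.integers(1, max_len))))
    return out


@pytest.fixture(scope="session")
def default_genome():
    """One default-condition simulated genome shared across tests."""
    return generate_genome(SimulationConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
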