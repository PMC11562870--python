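import numpy as np
import pytest

from epimark.core_io import GenomicInterval, Peak
from epimark.synthetic_data import SyntheticConfig, generate


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic study (jitter + spurious peaks on)."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free synthetic study: zero jitter, zero spurious peaks."""
    return generate(SyntheticConfig(seed=12, jitter_sd=0.0, spurious_rate=0.0))


def random_intervals(rng, n, genome_len=1_000_000, chroms=("chr1",), max_len=5000):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, genome_len - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_peaks(rng, n, **kw):
    return [
        Peak(iv, score=float(rng.uniform(0, 50)), neglog10p=float(rng.uniform(0, 20)))
        for iv in random_intervals(rng, n, **kw)
    ]
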