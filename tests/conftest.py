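import numpy as np
import pytest

from ffconcord import SimulationConfig, VariantRecord


@pytest.fixture
def small_config():
    """A 30-Mb single-chromosome pair: fast enough for replicated tests."""
    return SimulationConfig(
        seed=7,
        n_variants=600,
        chrom_lengths={"1": 30_000_000},
        cna_segments=[("1", 5_000_000, 10_000_000, 3)],
    )


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


def make_variant(chrom="1", pos=100, ref="C", alt="T", depth=100, alt_count=30):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         depth=depth, alt_count=alt_count)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
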