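import numpy as np
import pytest

from promprof import (
    GeneratorConfig,
    KmerPropertyTable,
    PromoterSet,
    generate_promoter_set,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20160324)


@pytest.fixture
def toy_r_table():
    """Asymmetric per-strand dinucleotide table with distinct values."""
    values = {}
    for i, a in enumerate("ACGT"):
        for j, b in enumerate("ACGT"):
            values[a + b] = 0.5 + 0.17 * i + 0.031 * j
    return KmerPropertyTable.from_dict(2, values, name="toy_R")


@pytest.fixture
def toy_t_table(rng):
    """Random per-strand tetranucleotide table."""
    return KmerPropertyTable(4, rng.uniform(0.5, 2.0, 256), name="toy_T")


@pytest.fixture
def random_set(rng):
    """50 random 60-nt sequences, uniform base composition, no N."""
    cfg = GeneratorConfig(n=50, length=60, tss_offset=50, seed=7)
    return generate_promoter_set(cfg)


@pytest.fixture
def poly_a_set():
    return PromoterSet(["A" * 60] * 5)


def make_uniform_set(n: int, seed: int, motifs=()) -> PromoterSet:
    cfg = GeneratorConfig(n=n, length=60, tss_offset=50, motifs=list(motifs), seed=seed)
    return generate_promoter_set(cfg)
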