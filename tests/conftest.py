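import numpy as np
import pandas as pd
import pytest

from feralscan.variants import GenotypeTable


def make_table(dosage, chrom="chr1A", positions=None, samples=None):
    """Build a GenotypeTable from a (samples x sites) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": ["A"] * m, "alt": ["T"] * m}
    )
    return GenotypeTable(variants=variants, dosage=dosage, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_table(rng):
    """60 samples x 120 sites of random inbred-style genotypes with missing."""
    p = rng.uniform(0.1, 0.9, size=120)
    dosage = 2 * (rng.random((60, 120)) < p).astype(np.int8)
    het = rng.random((60, 120)) < 0.02
    dosage[het] = 1
    dosage[rng.random((60, 120)) < 0.03] = -1
    return make_table(dosage)
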