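import numpy as np
import pandas as pd
import pytest

from chemohf.genotype_io import GenotypeMatrix, VARIANT_COLUMNS


def make_matrix(dosages, variant_ids=None, sample_ids=None, locus="TRPC6"):
    """Build a GenotypeMatrix from a plain dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variant_ids = variant_ids or [f"snp{j}" for j in range(m)]
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(n)]
    variants = pd.DataFrame(
        [(v, "11", 100 + j, "A", "G", locus) for j, v in enumerate(variant_ids)],
        columns=VARIANT_COLUMNS,
    )
    return GenotypeMatrix(sample_ids, variants, dosages)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 SNPs with one missing genotype."""
    return make_matrix([[0, 1], [1, 2], [np.nan, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
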