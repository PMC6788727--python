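import numpy as np
import pandas as pd
import pytest

from voxgene.genotypes import GenotypeMatrix


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """10 subjects x 6 SNPs over 2 genes / 2 chromosomes, no missing calls."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
    meta = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(6)],
            "gene": ["GA"] * 3 + ["GB"] * 3,
            "chrom": [1, 1, 1, 2, 2, 2],
            "pos": [100, 200, 300, 100, 200, 300],
        }
    ).set_index("snp")
    return GenotypeMatrix(calls=calls, snp_meta=meta, subject_ids=[f"p{i}" for i in range(10)])


def make_genotypes(calls, genes=None, chroms=None, subject_prefix="p"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    genes = genes or ["G1"] * m
    chroms = chroms or [1] * m
    meta = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(m)],
            "gene": genes,
            "chrom": chroms,
            "pos": np.arange(1, m + 1) * 100,
        }
    ).set_index("snp")
    return GenotypeMatrix(
        calls=calls, snp_meta=meta, subject_ids=[f"{subject_prefix}{i}" for i in range(n)]
    )
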