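import numpy as np
import pandas as pd
import pytest

from cisreg.genetics_core import GenotypeMatrix
from cisreg.synthetic_data import (
    HaplotypePool,
    default_haplotype_pool,
    make_four_study_fixture,
)


@pytest.fixture(scope="session")
def pool() -> HaplotypePool:
    return default_haplotype_pool()


@pytest.fixture(scope="session")
def fixture():
    """The four-study synthetic fixture at a fixed seed."""
    return make_four_study_fixture(1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def genotypes_from_dosages(dosages, variant_ids=None, positions=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix straight from a dosage array (test helper)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variant_ids = variant_ids or [f"v{j + 1}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions if positions is not None else np.arange(1, m + 1),
            "ref": "A",
            "alt": "G",
            "type": "SNP",
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        variant_ids=list(variant_ids),
        dosages=dosages,
        variant_meta=meta,
    )


def random_genotypes(
    rng: np.random.Generator, n: int, m: int, maf_range=(0.1, 0.5)
) -> GenotypeMatrix:
    """Independent binomial(2, maf) variants (no LD), polymorphic columns."""
    mafs = rng.uniform(*maf_range, size=m)
    while True:
        d = rng.binomial(2, mafs, size=(n, m)).astype(float)
        if (d.std(axis=0) > 0).all():
            return genotypes_from_dosages(d)
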