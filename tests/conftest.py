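import numpy as np
import pandas as pd
import pytest

from pprskit import simdata
from pprskit.io import GenotypeMatrix


def make_genotypes(dosages, positions=None, chrom=1, ids=None, eaf=None):
    """Build a GenotypeMatrix from a (samples x variants) array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    ids = ids or [f"v{j + 1}" for j in range(m)]
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    with np.errstate(invalid="ignore"):
        emp = np.nanmean(d, axis=0) / 2
    variants = pd.DataFrame({
        "variant_id": ids,
        "chrom": chrom if np.ndim(chrom) else [chrom] * m,
        "pos": positions,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf if eaf is not None else emp,
    })
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, d)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    cfg = simdata.default_config(seed=42, n_samples=4000, n_null_variants=30)
    gm, pheno = simdata.simulate_cohort(cfg)
    return cfg, gm, pheno


@pytest.fixture
def base_covariates(small_cohort):
    _, _, pheno = small_cohort
    return pheno[["age", "sex", "age2", "age_sex", "age2_sex"]].to_numpy(float)
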