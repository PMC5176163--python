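import numpy as np
import pandas as pd
import pytest

from admixjoint import CohortSimulator


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by read-only tests."""
    return CohortSimulator(n_ind=100, n_snps=400, n_related=12, seed=42).simulate()


@pytest.fixture(scope="session")
def null_samples():
    """Covariate/phenotype table with no genetic effects, n=200."""
    sim = CohortSimulator(n_ind=200, n_snps=200, n_related=0, seed=3)
    return sim.simulate()


def toy_snp_table(n, chrom=None):
    """Position-sorted SNP table for hand-built matrices."""
    chrom = chrom if chrom is not None else [1] * n
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, n + 1) * 1000, "ref": "A", "alt": "G"},
        index=pd.Index([f"s{i}" for i in range(n)], name="snp_id"),
    )
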