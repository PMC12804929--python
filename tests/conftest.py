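import numpy as np
import pandas as pd
import pytest

from complexpqtl import simdata
from complexpqtl.genio import GenotypeMatrix


def make_genotypes(dosage: np.ndarray, chroms=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw dosage array with minimal metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["1"] * m,
            "id": [f"v{j}" for j in range(m)],
            "cm": 0.0,
            "pos": np.arange(m) + 1,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosage, variants, [f"s{i}" for i in range(n)])


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 2000-sample, 60-variant cohort with covariates."""
    G = simdata.simulate_genotypes(
        simdata.GenotypeSimConfig(n_samples=2000, n_variants=60, seed=11)
    )
    S = simdata.simulate_covariates(2000, n_pcs=3, seed=12)
    return G, S


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
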