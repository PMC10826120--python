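import numpy as np
import pandas as pd
import pytest

from epitrio import CaseControlLabels, GenotypeMatrix, fixture_small


def random_cohort(rng: np.random.Generator, n_ind: int, n_snp: int, missing_rate: float = 0.1):
    """Arbitrary-valid genotype matrix + labels for I/O property tests."""
    values = rng.integers(0, 3, size=(n_ind, n_snp), dtype=np.int8)
    if missing_rate:
        values[rng.random(values.shape) < missing_rate] = -1
    meta = pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, n_snp).astype(str),
            "snp_id": [f"rs{i}" for i in range(n_snp)],
            "pos": np.sort(rng.integers(1, 10**8, n_snp)),
            "allele1": "A",
            "allele2": "G",
        }
    )
    g = GenotypeMatrix(values, meta, [f"i{j}" for j in range(n_ind)])
    status = rng.integers(0, 2, n_ind).astype(np.int8)
    # both classes non-empty
    status[0], status[-1] = 0, 1
    return g, CaseControlLabels(status)


@pytest.fixture(scope="session")
def toy_cohort():
    """The deterministic 60 x 12 cohort with one planted parity triplet."""
    return fixture_small()
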