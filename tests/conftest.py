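import numpy as np
import pandas as pd
import pytest

from panffpe.quant_matrix import QuantMatrix
from panffpe.synthetic import SyntheticConfig


def make_matrix(values_by_cohort: dict[str, np.ndarray], proteins=None, log2=True):
    """Build a QuantMatrix from per-cohort value blocks (NaN = missing).

    ``values_by_cohort`` maps cohort name → (proteins × samples) array of
    log2 intensities (converted to linear scale unless ``log2=False``).
    """
    blocks, sample_ids, cohorts = [], [], {}
    for cohort, block in values_by_cohort.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        ids = [f"{cohort}_{i + 1}" for i in range(block.shape[1])]
        sample_ids.extend(ids)
        cohorts.update({s: cohort for s in ids})
        blocks.append(block)
    data = np.concatenate(blocks, axis=1)
    if log2:
        data = 2.0**data
    n = data.shape[0]
    proteins = proteins or [f"P{i + 1}" for i in range(n)]
    lfq = pd.DataFrame(data, index=proteins, columns=sample_ids)
    return QuantMatrix(lfq, pd.Series(cohorts))


@pytest.fixture
def two_cohort_config():
    """Small two-cohort synthetic config for fast generator tests."""
    return SyntheticConfig(seed=7, cohorts=(("A", 20), ("B", 20)), n_proteins=300)


@pytest.fixture
def six_cohort_config():
    """Six cohorts of 40 samples, the scale used for recovery checks."""
    return SyntheticConfig(
        seed=11,
        cohorts=tuple((c, 40) for c in ("GBM", "OSCC", "DLBCL", "PDAC", "CRC", "MEL")),
        n_proteins=800,
    )
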