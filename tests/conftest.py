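"""Shared fixtures: small expression matrices and a simulated cohort."""

import numpy as np
import pandas as pd
import pytest

from gmicnet import ExpressionMatrix, GeneratorParams, simulate_dataset


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic cohort (seed 1): 6 factor modules + 2 marker blocks."""
    return simulate_dataset(GeneratorParams(seed=1))


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(rng.normal(8, 2, size=(12, 8)),
                        index=[f"G{i}" for i in range(12)],
                        columns=[f"S{j}" for j in range(8)])
    return ExpressionMatrix(data)


def two_block_matrix(seed=0, block=50, n=60, rho_loading=2.0):
    """Two planted co-expression blocks (within-correlation ~0.8), no overlap."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
    rows, truth = [], []
    for f, m in ((f1, 1), (f2, 2)):
        for _ in range(block):
            rows.append(rho_loading * f + rng.standard_normal(n))
            truth.append(m)
    data = pd.DataFrame(np.array(rows),
                        index=[f"G{i}" for i in range(2 * block)],
                        columns=[f"S{j}" for j in range(n)])
    return ExpressionMatrix(data), truth
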