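import numpy as np
import pandas as pd
import pytest

from epiretscore import MethylationMatrix


def make_matrix(chroms, positions, betas, samples, coverage=None):
    """Small hand-built matrix helper used across test modules."""
    idx = pd.MultiIndex.from_arrays([chroms, positions], names=["chrom", "pos"])
    beta = pd.DataFrame(np.asarray(betas, dtype=float), index=idx, columns=samples)
    cov = None
    if coverage is not None:
        cov = pd.DataFrame(np.asarray(coverage), index=idx, columns=samples)
    return MethylationMatrix(beta, cov)


@pytest.fixture
def two_group_matrix():
    """20 CpGs at 100-bp spacing on one chromosome; group B sits a uniform
    0.3 above group A (2 samples per group)."""
    n = 20
    positions = [1000 + 100 * i for i in range(n)]
    a = np.full((n, 2), 0.3)
    b = np.full((n, 2), 0.6)
    return make_matrix(["chr1"] * n, positions, np.hstack([a, b]),
                       ["a1", "a2", "b1", "b2"])
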