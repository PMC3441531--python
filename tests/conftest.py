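import numpy as np
import pandas as pd
import pytest

from samplenet.datatypes import ExpressionMatrix, SampleAdjacency


def random_adjacency(n: int, seed: int) -> SampleAdjacency:
    """Random symmetric weighted adjacency with unit diagonal."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.05, 0.95, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    ids = [f"s{i}" for i in range(n)]
    return SampleAdjacency(pd.DataFrame(a, index=ids, columns=ids), beta=None, kind="signed_cor")


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    return ExpressionMatrix.from_arrays(rng.normal(size=(30, 8)))


def naive_clustering_coefficient(a: np.ndarray) -> np.ndarray:
    """Triple-loop reference for the weighted clustering coefficient."""
    n = a.shape[0]
    b = a.copy()
    np.fill_diagonal(b, 0.0)
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        for l in range(n):
            if l == i:
                continue
            for m in range(n):
                if m == i or m == l:
                    continue
                num += b[i, l] * b[l, m] * b[m, i]
        s1 = sum(b[i, l] for l in range(n) if l != i)
        s2 = sum(b[i, l] ** 2 for l in range(n) if l != i)
        den = s1**2 - s2
        out[i] = 0.0 if abs(den) < 1e-12 else num / den
    return out
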