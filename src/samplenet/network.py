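"""Sample adjacency construction and network concepts.

A *sample network* treats each biological sample as a node.  Edges are
adjacency-transformed inter-sample correlations: for samples i and j,

    a_ij = ((cor(S_i, S_j) + 1) / 2) ** beta        (signed weighted, beta = 2)

which maps correlations from [-1, 1] into [0, 1] while preserving their
sign.  With beta = 2 the adjacency is close to the correlation whenever
correlations are high (> 0.6), which is typical among samples in genomic
data.

Node concepts
-------------
connectivity            k_i  = sum_{j != i} a_ij
scaled connectivity     K_i  = k_i / kmax
standardized            Z.K_i = (K_i - mean K) / sd(K)
clustering coefficient  C_i  = sum_{l!=i} sum_{m!=i,l} a_il a_lm a_mi
                               / ((sum_{l!=i} a_il)^2 - sum_{l!=i} a_il^2)
max adjacency ratio     MAR_i = sum_{j!=i} a_ij^2 / sum_{j!=i} a_ij

Network concepts
----------------
density (mean inter-sample adjacency, ISA), heterogeneity (coefficient
of variation of k), homogeneity = 1/(1 + heterogeneity^2), centralization,
and cor(K,C): the Spearman correlation between connectivity and
clustering coefficient across nodes.  cor(K,C) is near -1 in clean,
homogeneous sample networks and moves toward +1 as structure degrades.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CorrelationMatrix,
    ExpressionMatrix,
    NetworkSummary,
    NodeConceptTable,
    SampleAdjacency,
    SampleNetworkError,
)

__all__ = [
    "sample_correlation",
    "signed_power_adjacency",
    "euclidean_adjacency",
    "dichotomize_adjacency",
    "node_concepts",
    "network_summary",
    "spearman_corKC",
    "expected_corKC_factorizable",
    "build_adjacency",
]

_MIN_PAIR_OBS = 3


def sample_correlation(
    expr: ExpressionMatrix, method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise correlation between sample columns.

    Zero-variance features are excluded from all pairs (and reported in
    ``dropped_features``); missing values are handled by
    pairwise-complete observation.  Pairs with fewer than 3 complete
    observations are rejected.
    """
    if method not in ("pearson", "spearman"):
        raise SampleNetworkError(f"unknown correlation method: {method}")
    df = expr.data
    variances = df.var(axis=1, skipna=True)
    keep = variances > 0
    dropped = list(df.index[~keep])
    df = df.loc[keep]
    if df.shape[0] < 2:
        raise SampleNetworkError("degenerate input")

    notna = df.notna().to_numpy().astype(np.int64)
    n_used = notna.T @ notna
    if (n_used[~np.eye(len(df.columns), dtype=bool)] < _MIN_PAIR_OBS).any():
        raise SampleNetworkError("insufficient overlap")

    r = df.corr(method=method, min_periods=_MIN_PAIR_OBS)
    rv = r.to_numpy()
    np.fill_diagonal(rv, 1.0)
    rv = np.clip((rv + rv.T) / 2.0, -1.0, 1.0)
    r = pd.DataFrame(rv, index=r.index, columns=r.columns)
    n_used_df = pd.DataFrame(n_used, index=r.index, columns=r.columns)
    return CorrelationMatrix(
        r=r, method=method, n_features_used=n_used_df, dropped_features=dropped
    )


def signed_power_adjacency(
    corr: CorrelationMatrix, beta: float = 2.0
) -> SampleAdjacency:
    """Signed weighted adjacency a_ij = ((r_ij + 1)/2)^beta, diagonal 1."""
    if beta <= 0:
        raise SampleNetworkError("invalid power")
    a = ((corr.r.to_numpy() + 1.0) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return SampleAdjacency(
        a=pd.DataFrame(a, index=corr.r.index, columns=corr.r.columns),
        beta=beta,
        kind="signed_cor",
    )


def euclidean_adjacency(expr: ExpressionMatrix) -> SampleAdjacency:
    """Distance-based adjacency a_ij = 1 - d_ij / max d, diagonal 1.

    Requires complete data (no missing values).
    """
    df = expr.data
    if df.isna().any().any():
        raise SampleNetworkError("complete data required")
    x = df.to_numpy().T  # samples x features
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    dmax = d.max()
    if dmax == 0:
        raise SampleNetworkError("degenerate distances")
    a = 1.0 - d / dmax
    np.fill_diagonal(a, 1.0)
    return SampleAdjacency(
        a=pd.DataFrame(a, index=df.columns, columns=df.columns),
        beta=None,
        kind="euclidean",
    )


def dichotomize_adjacency(adj: SampleAdjacency, tau: float) -> SampleAdjacency:
    """Hard-threshold a weighted adjacency: a_ij >= tau -> 1, else 0."""
    if not (0 < tau <= 1):
        raise SampleNetworkError("invalid threshold")
    a = (adj.a.to_numpy() >= tau).astype(float)
    np.fill_diagonal(a, 1.0)
    return SampleAdjacency(
        a=pd.DataFrame(a, index=adj.a.index, columns=adj.a.columns),
        beta=adj.beta,
        kind="binary",
    )


def node_concepts(adj: SampleAdjacency) -> NodeConceptTable:
    """Per-node connectivity, clustering coefficient and MAR.

    The clustering-coefficient numerator sum_{l!=i, m!=i,l} a_il a_lm a_mi
    equals diag(B^3) for B the adjacency with zeroed diagonal, which is
    what is computed here.  Nodes whose denominator k_i^2 - sum a_il^2 is
    zero (fewer than two effective neighbours) get C_i = 0 and are
    flagged, not rejected.
    """
    n = adj.n_samples
    if n < 3:
        raise SampleNetworkError("network too small")
    b = adj.offdiag()
    k = b.sum(axis=1)
    kmax = float(k.max())
    if kmax == 0:
        raise SampleNetworkError("empty network")
    K = k / kmax

    b2 = b @ b
    numer = np.einsum("ij,ji->i", b2, b)  # diag(B^3)
    sum_sq = (b**2).sum(axis=1)
    denom = k**2 - sum_sq
    zero_den = np.isclose(denom, 0.0, atol=1e-12)
    C = np.where(zero_den, 0.0, numer / np.where(zero_den, 1.0, denom))
    C = np.clip(C, 0.0, None)

    with np.errstate(invalid="ignore", divide="ignore"):
        MAR = np.where(k > 0, sum_sq / np.where(k > 0, k, 1.0), 0.0)

    def _z(x: np.ndarray) -> tuple[np.ndarray, bool]:
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            return np.zeros_like(x), True
        return (x - x.mean()) / sd, False

    ZK, flag_k = _z(K)
    ZC, flag_c = _z(C)

    table = pd.DataFrame(
        {"k": k, "K": K, "ZK": ZK, "C": C, "ZC": ZC, "MAR": MAR},
        index=adj.a.index,
    )
    return NodeConceptTable(
        table=table,
        kmax=kmax,
        zero_variance_K=flag_k,
        zero_variance_C=flag_c,
        zero_denominator_C=list(table.index[zero_den]),
    )


def spearman_corKC(
    k: np.ndarray, C: np.ndarray, method: str = "t"
) -> tuple[float, float]:
    """Spearman correlation of (k, C) with a two-sided p-value.

    ``method='t'`` uses the usual t approximation with df = n - 2
    (average ranks on ties); ``method='exact'`` enumerates pairings
    exactly and is available for n <= 10.

    Returns (nan, nan) when either vector has zero variance.
    """
    k = np.asarray(k, dtype=float)
    C = np.asarray(C, dtype=float)
    if k.std() == 0 or C.std() == 0:
        return float("nan"), float("nan")
    if method == "exact":
        n = len(k)
        if n > 10:
            raise SampleNetworkError("exact p-value available only for n <= 10")
        rho = float(stats.spearmanr(k, C).statistic)
        rk = stats.rankdata(k)
        rc = stats.rankdata(C)
        rk = (rk - rk.mean()) / rk.std()
        rc = (rc - rc.mean()) / rc.std()
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (rc[perms] * rk).mean(axis=1)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    res = stats.spearmanr(k, C)
    return float(res.statistic), float(res.pvalue)


def network_summary(
    adj: SampleAdjacency,
    corr: CorrelationMatrix | None = None,
    concepts: NodeConceptTable | None = None,
) -> NetworkSummary:
    """Whole-network concepts for a sample adjacency matrix.

    ``mean_cor`` is taken from ``corr`` when given; for a signed power
    adjacency it is otherwise recovered exactly by inverting the
    adjacency map (r = 2 a^(1/beta) - 1), and is NaN for other kinds.
    Heterogeneity uses population moments so that
    homogeneity = 1/(1 + heterogeneity^2) = (sum k)^2 / (n sum k^2).
    """
    n = adj.n_samples
    if n < 3:
        raise SampleNetworkError("network too small")
    if concepts is None:
        concepts = node_concepts(adj)
    k = concepts.table["k"].to_numpy()
    C = concepts.table["C"].to_numpy()

    b = adj.offdiag()
    density = float(b.sum() / (n * (n - 1)))

    if corr is not None:
        mean_cor = corr.mean_offdiag()
    elif adj.kind == "signed_cor" and adj.beta:
        r = 2.0 * b ** (1.0 / adj.beta) - 1.0
        np.fill_diagonal(r, 0.0)
        mean_cor = float(r.sum() / (n * (n - 1)))
    else:
        mean_cor = float("nan")

    mean_k = k.mean()
    if mean_k == 0:
        heterogeneity = float("nan")
        homogeneity = float("nan")
    else:
        heterogeneity = float(np.sqrt(k.var(ddof=0)) / mean_k)
        homogeneity = 1.0 / (1.0 + heterogeneity**2)

    centralization = float((n / (n - 2)) * (concepts.kmax / (n - 1) - density))
    corKC, corKC_p = spearman_corKC(k, C)

    return NetworkSummary(
        n_samples=n,
        density=density,
        mean_cor=mean_cor,
        heterogeneity=heterogeneity,
        homogeneity=homogeneity,
        centralization=centralization,
        decentralization=1.0 - centralization,
        corKC=corKC,
        corKC_p=corKC_p,
        mean_MAR=float(concepts.table["MAR"].mean()),
        mean_C=float(C.mean()),
    )


def expected_corKC_factorizable(heterogeneity: float) -> float:
    """Closed-form cor(K,C) approximation for exactly factorizable networks.

    For adjacencies of the form a_ij = CF(i) CF(j), cor(K,C) is
    approximately 0.96 - 2.19/(1 + heterogeneity^2).  The value is
    reported unclamped: it is an approximation of a correlation and may
    fall below -1 (e.g. -1.23 at zero heterogeneity).
    """
    if heterogeneity < 0:
        raise SampleNetworkError("invalid heterogeneity")
    return 0.96 - 2.19 / (1.0 + heterogeneity**2)


def build_adjacency(
    expr: ExpressionMatrix,
    corr_method: str = "pearson",
    beta: float = 2.0,
    kind: str = "signed_cor",
) -> tuple[SampleAdjacency, CorrelationMatrix | None]:
    """Convenience: expression matrix -> (adjacency, correlation)."""
    if kind == "signed_cor":
        corr = sample_correlation(expr, method=corr_method)
        return signed_power_adjacency(corr, beta=beta), corr
    if kind == "euclidean":
        return euclidean_adjacency(expr), None
    raise SampleNetworkError(f"unknown adjacency kind: {kind}")
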