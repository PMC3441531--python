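"""Core containers for sample-network analysis.

All containers wrap :class:`pandas.DataFrame`/:class:`pandas.Series`
objects so that sample and feature identifiers travel with the numbers.
Matrices are genes x samples throughout (features in rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CorrelationMatrix",
    "SampleAdjacency",
    "NodeConceptTable",
    "NetworkSummary",
    "TraitTable",
    "GeneSetCollection",
    "ModuleEigengene",
]


class SampleNetworkError(ValueError):
    """Raised for invalid inputs to sample-network operations."""


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with unique row/column identifiers.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.  Missing values are allowed (they are
        handled pairwise by the correlation step).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise SampleNetworkError("duplicate identifier")
        if self.data.shape[1] < 2:
            raise SampleNetworkError("at least 2 samples required")
        self.data = self.data.astype(float)

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        values = np.asarray(values, dtype=float)
        n_feat, n_samp = values.shape
        if feature_ids is None:
            feature_ids = [f"g{i + 1}" for i in range(n_feat)]
        if sample_ids is None:
            sample_ids = [f"s{j + 1}" for j in range(n_samp)]
        return cls(pd.DataFrame(values, index=list(feature_ids), columns=list(sample_ids)))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids), :])


@dataclass
class CorrelationMatrix:
    """Pairwise inter-sample correlations (symmetric, unit diagonal)."""

    r: pd.DataFrame
    method: str = "pearson"
    n_features_used: pd.DataFrame | None = None
    dropped_features: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def n_samples(self) -> int:
        return self.r.shape[0]

    def mean_offdiag(self) -> float:
        v = self.r.to_numpy()
        n = v.shape[0]
        return float((v.sum() - np.trace(v)) / (n * (n - 1)))


@dataclass
class SampleAdjacency:
    """Symmetric sample adjacency matrix with entries in [0, 1].

    The diagonal is stored as 1 but is always excluded from
    connectivity, density, clustering-coefficient and MAR sums.
    """

    a: pd.DataFrame
    beta: float | None = 2.0
    kind: str = "signed_cor"  # one of {signed_cor, euclidean, binary}

    def __post_init__(self) -> None:
        v = self.a.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise SampleNetworkError("adjacency must be square")
        if np.nanmin(v) < -1e-12 or np.nanmax(v) > 1 + 1e-12:
            raise SampleNetworkError("adjacency entries must lie in [0, 1]")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise SampleNetworkError("adjacency must be symmetric")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.a.index)

    @property
    def n_samples(self) -> int:
        return self.a.shape[0]

    def offdiag(self) -> np.ndarray:
        """Adjacency with a zeroed diagonal, as a plain array."""
        v = self.a.to_numpy(copy=True)
        np.fill_diagonal(v, 0.0)
        return v


@dataclass
class NodeConceptTable:
    """Per-sample network concepts: k, K, Z.K, C, Z.C, MAR."""

    table: pd.DataFrame  # columns: k, K, ZK, C, ZC, MAR
    kmax: float
    zero_variance_K: bool = False
    zero_variance_C: bool = False
    zero_denominator_C: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]


@dataclass
class NetworkSummary:
    """Whole-network concepts for one sample network."""

    n_samples: int
    density: float
    mean_cor: float
    heterogeneity: float
    homogeneity: float
    centralization: float
    decentralization: float
    corKC: float  # NaN when undefined (zero variance in k or C)
    corKC_p: float
    mean_MAR: float = float("nan")
    mean_C: float = float("nan")

    @property
    def corKC_defined(self) -> bool:
        return not np.isnan(self.corKC)

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "density": self.density,
            "mean_cor": self.mean_cor,
            "heterogeneity": self.heterogeneity,
            "homogeneity": self.homogeneity,
            "centralization": self.centralization,
            "decentralization": self.decentralization,
            "corKC": None if np.isnan(self.corKC) else self.corKC,
            "corKC_p": None if np.isnan(self.corKC_p) else self.corKC_p,
            "mean_MAR": None if np.isnan(self.mean_MAR) else self.mean_MAR,
            "mean_C": None if np.isnan(self.mean_C) else self.mean_C,
        }
        return d


@dataclass
class TraitTable:
    """Per-sample covariates (categorical or numeric), indexed by sample id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise SampleNetworkError("duplicate identifier")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariates(self) -> list[str]:
        return list(self.data.columns)

    def get(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise SampleNetworkError("unknown covariate")
        return self.data[name]

    def aligned_to(self, sample_ids: Sequence[str]) -> "TraitTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise SampleNetworkError(
                f"samples missing from trait table: {missing[:5]}"
            )
        return TraitTable(self.data.loc[list(sample_ids)])


@dataclass
class GeneSetCollection:
    """Named gene sets (module label -> list of feature ids)."""

    sets: Mapping[str, list[str]]
    n_duplicates_removed: int = 0

    def __post_init__(self) -> None:
        self.sets = {k: list(v) for k, v in self.sets.items()}
        for name, members in self.sets.items():
            if len(members) == 0:
                raise SampleNetworkError(f"empty gene set: {name}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets.keys())


@dataclass
class ModuleEigengene:
    """First principal component of a module's expression submatrix.

    ``values`` has one entry per sample and unit Euclidean norm; the sign
    is oriented so the eigengene correlates non-negatively with the mean
    standardized expression profile of the module.
    """

    values: pd.Series
    variance_explained: float
    module: str = ""
    n_genes_used: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)
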