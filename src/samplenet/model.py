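"""Model/results interface for sample-network analysis.

:class:`SampleNetwork` is constructed from a genes x samples expression
matrix (or directly from a precomputed adjacency); :meth:`SampleNetwork.fit`
builds the network and returns a :class:`SampleNetworkResults` holding
the adjacency, the per-sample node concepts, the whole-network summary
and a printable ``summary()`` table.  Outlier detection and plotting
hang off the results object.

Example
-------
>>> import pandas as pd
>>> from samplenet import SampleNetwork
>>> net = SampleNetwork.from_dataframe(df)      # genes x samples
>>> res = net.fit()
>>> print(res.summary())
>>> res.node_concepts.head()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    SampleAdjacency,
    SampleNetworkError,
    TraitTable,
)
from .network import (
    build_adjacency,
    network_summary,
    node_concepts,
    sample_correlation,
    signed_power_adjacency,
)

__all__ = ["SampleNetwork", "SampleNetworkResults"]


class SampleNetwork:
    """A weighted correlation network whose nodes are samples.

    Parameters
    ----------
    expr
        Expression matrix (genes in rows, samples in columns).
    corr_method
        Inter-sample correlation estimator, ``pearson`` (default) or
        ``spearman``.
    beta
        Soft-threshold power of the signed adjacency
        a_ij = ((r_ij + 1)/2)^beta; default 2.
    kind
        ``signed_cor`` (default) or ``euclidean``.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        corr_method: str = "pearson",
        beta: float = 2.0,
        kind: str = "signed_cor",
    ) -> None:
        self.expr = expr
        self.corr_method = corr_method
        self.beta = beta
        self.kind = kind
        self._adjacency: SampleAdjacency | None = None

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        samples_in_rows: bool = False,
        **kwargs,
    ) -> "SampleNetwork":
        """Build from a DataFrame; set ``samples_in_rows`` to transpose."""
        if samples_in_rows:
            df = df.T
        return cls(ExpressionMatrix(df), **kwargs)

    @classmethod
    def from_adjacency(cls, adj: SampleAdjacency) -> "SampleNetwork":
        obj = cls.__new__(cls)
        obj.expr = None
        obj.corr_method = None
        obj.beta = adj.beta
        obj.kind = adj.kind
        obj._adjacency = adj
        return obj

    def fit(self) -> "SampleNetworkResults":
        """Construct the adjacency and compute all network concepts."""
        if self._adjacency is not None:
            adj, corr = self._adjacency, None
        else:
            adj, corr = build_adjacency(
                self.expr, corr_method=self.corr_method,
                beta=self.beta, kind=self.kind,
            )
        concepts = node_concepts(adj)
        summ = network_summary(adj, corr=corr, concepts=concepts)
        return SampleNetworkResults(self, adj, corr, concepts, summ)


class SampleNetworkResults:
    """Fitted sample network: adjacency, node concepts and summary statistics.

    Attributes
    ----------
    adjacency : SampleAdjacency
    correlation : CorrelationMatrix or None
    node_concepts : pandas.DataFrame
        Per-sample k, K, Z.K, C, Z.C, MAR.
    network_summary : NetworkSummary
        density/ISA, mean correlation, heterogeneity, homogeneity,
        (de)centralization, cor(K,C) with p-value.
    """

    def __init__(self, model, adjacency, correlation, concepts, summary):
        self.model = model
        self.adjacency = adjacency
        self.correlation = correlation
        self._concepts = concepts
        self.network_summary = summary

    @property
    def node_concepts(self) -> pd.DataFrame:
        return self._concepts.table

    @property
    def concept_flags(self) -> dict:
        return {
            "zero_variance_K": self._concepts.zero_variance_K,
            "zero_variance_C": self._concepts.zero_variance_C,
            "zero_denominator_C": self._concepts.zero_denominator_C,
        }

    @property
    def corKC(self) -> float:
        return self.network_summary.corKC

    def outlier_candidates(self, threshold: float = -2.0) -> list[str]:
        """Samples whose standardized connectivity falls below ``threshold``."""
        zk = self.node_concepts["ZK"]
        return zk.index[zk < threshold].tolist()

    def summary(self) -> str:
        s = self.network_summary
        corkc = "undefined" if np.isnan(s.corKC) else f"{s.corKC:10.4f}"
        corkc_p = "" if np.isnan(s.corKC_p) else f"  (p = {s.corKC_p:.3g})"
        lines = [
            "Sample Network Results",
            "=" * 46,
            f"{'No. samples:':<28}{s.n_samples:>10d}",
            f"{'Adjacency kind:':<28}{self.adjacency.kind:>10}",
            f"{'Soft power (beta):':<28}{str(self.adjacency.beta):>10}",
            "-" * 46,
            f"{'Density (mean ISA):':<28}{s.density:>10.4f}",
            f"{'Mean correlation:':<28}{s.mean_cor:>10.4f}",
            f"{'Heterogeneity:':<28}{s.heterogeneity:>10.4f}",
            f"{'Homogeneity:':<28}{s.homogeneity:>10.4f}",
            f"{'Centralization:':<28}{s.centralization:>10.4f}",
            f"{'Decentralization:':<28}{s.decentralization:>10.4f}",
            f"{'Mean clustering coef.:':<28}{s.mean_C:>10.4f}",
            f"{'Mean MAR:':<28}{s.mean_MAR:>10.4f}",
            f"{'cor(K,C) [Spearman]:':<28}{corkc}{corkc_p}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot_ck_curve(self, ax=None, labels: pd.Series | None = None):
        """Scatter of Z.C against Z.K (the standardized C(k) curve)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.node_concepts
        if labels is None:
            ax.scatter(t["ZK"], t["ZC"])
        else:
            labels = labels.reindex(t.index)
            for level in labels.dropna().unique():
                mask = labels == level
                ax.scatter(t.loc[mask, "ZK"], t.loc[mask, "ZC"], label=str(level))
            ax.legend()
        ax.set_xlabel("Z.K (standardized connectivity)")
        ax.set_ylabel("Z.C (standardized clustering coefficient)")
        s = self.network_summary
        if not np.isnan(s.corKC):
            ax.set_title(f"cor(K,C) = {s.corKC:.2f}")
        return ax

    def plot_dendrogram(self, ax=None):
        """Average-linkage clustering of samples on dissimilarity 1 - ISA."""
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        if ax is None:
            _, ax = plt.subplots()
        d = 1.0 - self.adjacency.a.to_numpy()
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        link = hierarchy.average(squareform(d, checks=False))
        hierarchy.dendrogram(link, labels=self.adjacency.sample_ids, ax=ax)
        ax.set_ylabel("1 - ISA")
        return ax
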