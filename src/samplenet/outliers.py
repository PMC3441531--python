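"""Outlier detection, normalization, and covariate screening.

The outlier procedure builds the signed (beta = 2) sample network,
standardizes the connectivity (Z.K), removes every sample falling below
a threshold (default -2), rebuilds the network on the survivors, and
repeats.  Removal happens within groups of samples defined by a
covariate (e.g. brain region or batch), because connectivity is only
comparable among samples expected to be alike.  As outliers are shed,
the network's density rises and cor(K,C) approaches -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ExpressionMatrix,
    NetworkSummary,
    NodeConceptTable,
    SampleNetworkError,
    TraitTable,
)
from .network import build_adjacency, network_summary, node_concepts

__all__ = [
    "OutlierReport",
    "detect_outliers",
    "quantile_normalize",
    "covariate_screen",
    "align_batches",
]

MIN_GROUP_SIZE = 4  # network concepts need n >= 3; the Fisher test needs n >= 4


@dataclass
class RemovalRound:
    round_index: int
    group: str | None
    removed: list[str]
    zk_at_removal: dict[str, float]
    summary: NetworkSummary


@dataclass
class OutlierReport:
    threshold: float
    rounds: list[RemovalRound] = field(default_factory=list)
    final_sample_ids: list[str] = field(default_factory=list)
    stopped_by_size_guard: bool = False

    @property
    def removed_sample_ids(self) -> list[str]:
        return [s for r in self.rounds for s in r.removed]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_removed": len(self.removed_sample_ids),
            "removed_sample_ids": self.removed_sample_ids,
            "final_sample_ids": self.final_sample_ids,
            "stopped_by_size_guard": self.stopped_by_size_guard,
            "rounds": [
                {
                    "round": r.round_index,
                    "group": r.group,
                    "removed": r.removed,
                    "zk_at_removal": r.zk_at_removal,
                    "network": r.summary.to_dict(),
                }
                for r in self.rounds
            ],
        }


def detect_outliers(
    expr: ExpressionMatrix,
    threshold: float = -2.0,
    traits: TraitTable | None = None,
    group_by: str | None = None,
    max_rounds: int = 10,
    mode: str = "batch",
    corr_method: str = "pearson",
    beta: float = 2.0,
) -> OutlierReport:
    """Iterative Z.K-threshold outlier removal.

    ``mode='batch'`` (default) removes all samples with Z.K below the
    threshold each round; ``mode='single'`` removes only the lowest one
    per round.  Iteration within a group stops when no sample falls
    below the threshold, ``max_rounds`` is reached, or removal would
    shrink the group below 4 samples.
    """
    if mode not in ("batch", "single"):
        raise SampleNetworkError(f"unknown removal mode: {mode}")
    if group_by is not None:
        if traits is None:
            raise SampleNetworkError("group_by requires a trait table")
        labels = traits.aligned_to(expr.sample_ids).get(group_by)
        groups = {str(g): list(labels.index[labels == g]) for g in labels.unique()}
    else:
        groups = {None: expr.sample_ids}

    report = OutlierReport(threshold=threshold)
    survivors: list[str] = []
    for gname, members in groups.items():
        if len(members) < MIN_GROUP_SIZE:
            raise SampleNetworkError("group too small")
        current = list(members)
        for round_idx in range(1, max_rounds + 1):
            sub = expr.subset_samples(current)
            adj, corr = build_adjacency(sub, corr_method=corr_method, beta=beta)
            concepts = node_concepts(adj)
            zk = concepts.table["ZK"]
            below = zk.index[zk < threshold].tolist()
            if not below:
                break
            if mode == "single":
                below = [zk.idxmin()]
            if len(current) - len(below) < MIN_GROUP_SIZE:
                # drop the worst samples only down to the size floor
                below = zk.loc[below].sort_values().index.tolist()
                below = below[: len(current) - MIN_GROUP_SIZE]
                report.stopped_by_size_guard = True
            if not below:
                break
            summ = network_summary(adj, corr=corr, concepts=concepts)
            report.rounds.append(
                RemovalRound(
                    round_index=round_idx,
                    group=gname,
                    removed=list(below),
                    zk_at_removal={s: float(zk[s]) for s in below},
                    summary=summ,
                )
            )
            current = [s for s in current if s not in below]
            if report.stopped_by_size_guard:
                break
        survivors.extend(current)

    report.final_sample_ids = [s for s in expr.sample_ids if s in set(survivors)]
    return report


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Classic reference-distribution quantile normalization.

    Each sample column is sorted, the reference distribution is the
    across-sample mean at each rank, and values are mapped back by each
    column's original ranks; tied values receive the mean of their tied
    reference values.  Afterwards every column holds the same multiset
    of values (up to tie-averaging).
    """
    df = expr.data
    if df.isna().any().any():
        raise SampleNetworkError("complete data required")
    x = df.to_numpy()
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties: average the reference values assigned within each tied run
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=assigned)
            assigned = sums[inv] / counts[inv]
        out[:, j] = assigned
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def covariate_screen(
    concepts: NodeConceptTable,
    traits: TraitTable,
    metrics: tuple[str, ...] = ("ZK", "ZC", "MAR"),
) -> pd.DataFrame:
    """Test each sample covariate against each node metric.

    Categorical covariates use a Kruskal-Wallis test across levels;
    numeric covariates use a Spearman correlation test.  Returns one row
    per (covariate, metric) with the test name, statistic and p-value;
    constant covariates are reported as ``not testable``.
    """
    aligned = traits.aligned_to(concepts.sample_ids)
    rows = []
    for cov in aligned.covariates:
        values = aligned.data[cov]
        numeric = pd.api.types.is_numeric_dtype(values)
        for metric in metrics:
            y = concepts.table[metric]
            if values.nunique(dropna=True) < 2:
                rows.append(
                    {"covariate": cov, "metric": metric, "test": None,
                     "statistic": np.nan, "p": np.nan, "status": "not testable"}
                )
                continue
            if numeric:
                mask = values.notna()
                res = stats.spearmanr(values[mask], y[mask])
                rows.append(
                    {"covariate": cov, "metric": metric, "test": "spearman",
                     "statistic": float(res.statistic), "p": float(res.pvalue),
                     "status": "ok"}
                )
            else:
                samples = [
                    y[values == level].to_numpy()
                    for level in values.dropna().unique()
                ]
                try:
                    res = stats.kruskal(*samples)
                    rows.append(
                        {"covariate": cov, "metric": metric, "test": "kruskal",
                         "statistic": float(res.statistic),
                         "p": float(res.pvalue), "status": "ok"}
                    )
                except ValueError:
                    rows.append(
                        {"covariate": cov, "metric": metric, "test": "kruskal",
                         "statistic": np.nan, "p": np.nan,
                         "status": "not testable"}
                    )
    return pd.DataFrame(rows)


def align_batches(
    expr: ExpressionMatrix,
    traits: TraitTable,
    batch_by: str,
    combat_hook=None,
) -> ExpressionMatrix:
    """Per-batch location-scale alignment of sample distributions.

    This is a simple alignment — each batch's per-gene mean and SD are
    mapped onto the pooled ones — NOT an empirical-Bayes batch model.
    A callable ``combat_hook(values, batch_labels) -> values`` may be
    supplied to delegate to an external batch-correction implementation
    instead.
    """
    labels = traits.aligned_to(expr.sample_ids).get(batch_by)
    x = expr.data
    if combat_hook is not None:
        corrected = combat_hook(x.to_numpy(), labels.to_numpy())
        return ExpressionMatrix(
            pd.DataFrame(corrected, index=x.index, columns=x.columns)
        )
    pooled_mean = x.mean(axis=1)
    pooled_sd = x.std(axis=1, ddof=1).replace(0, 1.0)
    out = x.copy()
    for level in labels.unique():
        cols = labels.index[labels == level]
        block = x[cols]
        bmean = block.mean(axis=1)
        bsd = block.std(axis=1, ddof=1).replace(0, 1.0)
        out[cols] = (
            block.sub(bmean, axis=0).div(bsd, axis=0).mul(pooled_sd, axis=0)
            .add(pooled_mean, axis=0)
        )
    return ExpressionMatrix(out)
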