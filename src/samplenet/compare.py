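"""Comparing network topology between groups of samples.

Two sample networks (one per group) can differ in the shape of their
standardized C(k) curves — the scatter of Z.C against Z.K — summarized
by cor(K,C).  The difference between the groups' cor(K,C) values is
tested with the classic Fisher-z test for two correlations from
independent samples:

    z = atanh(r),    z_diff = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3))

with a two-sided p-value from the standard normal distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, SampleNetworkError, TraitTable
from .network import build_adjacency, network_summary, node_concepts

__all__ = ["fisher_z", "compare_corKC", "ck_curve", "GroupComparison", "CKCurveTable"]

_CLAMP = 1.0 - 1e-15


@dataclass
class GroupComparison:
    """Fisher-z comparison of cor(K,C) between two sample networks."""

    r1: float
    r2: float
    n1: int
    n2: int
    z1: float
    z2: float
    z_diff: float
    p: float
    alternative: str = "two-sided"
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "corKC_group1": self.r1,
            "corKC_group2": self.r2,
            "n1": self.n1,
            "n2": self.n2,
            "z1": self.z1,
            "z2": self.z2,
            "z_diff": self.z_diff,
            "p": self.p,
            "alternative": self.alternative,
            "clamped": self.clamped,
        }


@dataclass
class CKCurveTable:
    """Per-sample Z.K/Z.C values with group labels and per-group cor(K,C)."""

    table: pd.DataFrame  # columns: ZK, ZC, group (indexed by sample id)
    group_corKC: pd.DataFrame  # per group: corKC, corKC_p, n
    joint: bool


def fisher_z(r: float) -> float:
    """Fisher transformation atanh(r); |r| >= 1 is clamped and flagged."""
    if abs(r) >= 1:
        warnings.warn(
            "correlation at or beyond +/-1 clamped before Fisher transform",
            stacklevel=2,
        )
        r = np.sign(r) * _CLAMP
    return float(np.arctanh(r))


def compare_corKC(
    r1: float, n1: int, r2: float, n2: int, alternative: str = "two-sided"
) -> GroupComparison:
    """Test whether two cor(K,C) values differ (Fisher z, normal reference).

    Each group's network must have been built and standardized
    independently before its cor(K,C) enters here.  Requires at least 4
    samples per group (the joint standard error uses n - 3).
    """
    if n1 <= 3 or n2 <= 3:
        raise SampleNetworkError("group too small for Fisher test")
    clamped = bool(abs(r1) >= 1 or abs(r2) >= 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z1, z2 = fisher_z(r1), fisher_z(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_diff = (z1 - z2) / se
    if alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z_diff))
    elif alternative == "greater":
        p = stats.norm.sf(z_diff)
    elif alternative == "less":
        p = stats.norm.cdf(z_diff)
    else:
        raise SampleNetworkError(f"unknown alternative: {alternative}")
    return GroupComparison(
        r1=float(r1), r2=float(r2), n1=int(n1), n2=int(n2),
        z1=z1, z2=z2, z_diff=float(z_diff), p=float(max(p, 5e-324)),
        alternative=alternative, clamped=clamped,
    )


def ck_curve(
    expr: ExpressionMatrix,
    traits: TraitTable,
    group_by: str,
    joint: bool = False,
    corr_method: str = "pearson",
    beta: float = 2.0,
) -> CKCurveTable:
    """Standardized C(k) curve table, by group.

    ``joint=True`` builds one network over all samples and labels each
    point by its group; ``joint=False`` builds one network per group, so
    Z.K/Z.C are standardized within each group's own network.  The two
    modes can disagree substantially — even in sign — which is itself
    informative about between-group structure.
    """
    labels = traits.aligned_to(expr.sample_ids).get(group_by)
    groups = labels.dropna().unique().tolist()
    for g in groups:
        if (labels == g).sum() < 4:
            raise SampleNetworkError("group too small")

    rows = []
    per_group = []
    if joint:
        adj, _ = build_adjacency(expr, corr_method=corr_method, beta=beta)
        concepts = node_concepts(adj)
        t = concepts.table[["ZK", "ZC"]].copy()
        t["group"] = labels.reindex(t.index)
        rows.append(t)
        for g in groups:
            sub = t[t["group"] == g]
            rho = stats.spearmanr(sub["ZK"], sub["ZC"])
            per_group.append(
                {"group": g, "corKC": float(rho.statistic),
                 "corKC_p": float(rho.pvalue), "n": len(sub)}
            )
    else:
        for g in groups:
            ids = labels.index[labels == g]
            sub_expr = expr.subset_samples(list(ids))
            adj, corr = build_adjacency(sub_expr, corr_method=corr_method, beta=beta)
            concepts = node_concepts(adj)
            summ = network_summary(adj, corr=corr, concepts=concepts)
            t = concepts.table[["ZK", "ZC"]].copy()
            t["group"] = g
            rows.append(t)
            per_group.append(
                {"group": g, "corKC": summ.corKC, "corKC_p": summ.corKC_p,
                 "n": len(ids)}
            )
    table = pd.concat(rows)
    group_df = pd.DataFrame(per_group).set_index("group")
    return CKCurveTable(table=table, group_corKC=group_df, joint=joint)


def compare_groups(
    expr: ExpressionMatrix,
    traits: TraitTable,
    group_by: str,
    corr_method: str = "pearson",
    beta: float = 2.0,
    alternative: str = "two-sided",
) -> GroupComparison:
    """Build one network per group (exactly two) and Fisher-test their cor(K,C)."""
    curve = ck_curve(
        expr, traits, group_by, joint=False, corr_method=corr_method, beta=beta
    )
    if len(curve.group_corKC) != 2:
        raise SampleNetworkError("exactly two groups required")
    (g1, row1), (g2, row2) = curve.group_corKC.iterrows()
    return compare_corKC(
        row1["corKC"], int(row1["n"]), row2["corKC"], int(row2["n"]),
        alternative=alternative,
    )
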