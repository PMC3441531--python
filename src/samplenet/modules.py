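"""Module sample networks: eigengenes, differential expression, and the module scan.

A *module* is a named gene set.  Its eigengene (ME) is the first
principal component of the module's standardized expression submatrix —
one value per sample summarizing the module's characteristic expression
pattern.  The module scan builds one sample network per group restricted
to each module's genes, compares the groups' cor(K,C) with the Fisher-z
test, and tests the ME for differential expression with Student's
t-test; both p-value columns get Bonferroni flags at 0.05 / (number of
modules scanned).  Differential expression of the ME and differences in
module network topology are complementary: a module can separate sample
groups topologically even when its eigengene shows no mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compare import compare_corKC
from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    ModuleEigengene,
    SampleNetworkError,
    TraitTable,
)
from .network import build_adjacency, network_summary

__all__ = [
    "module_eigengene",
    "module_de_test",
    "gene_de_table",
    "module_scan",
    "me_regression",
    "ModuleScanTable",
]


def module_eigengene(
    expr: ExpressionMatrix, genes, module: str = ""
) -> ModuleEigengene:
    """First principal component of a module's standardized submatrix.

    Genes are standardized (mean 0, SD 1 across samples) before the SVD
    so that genes on larger scales do not dominate.  The eigengene is
    the first right-singular vector (unit norm), sign-oriented so its
    correlation with the module's mean standardized profile is
    non-negative (first-entry-nonnegative as a degenerate fallback).
    """
    genes = [g for g in genes if g in expr.data.index]
    sub = expr.data.loc[genes]
    sds = sub.std(axis=1, ddof=1)
    sub = sub.loc[sds > 0]
    if sub.shape[0] < 2:
        raise SampleNetworkError("module too small")
    x = sub.to_numpy()
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    me = vt[0]
    mean_profile = x.mean(axis=0)
    orient = float(np.dot(me, mean_profile))
    if orient < 0:
        me = -me
    elif orient == 0 and me[np.argmax(np.abs(me) > 0)] < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return ModuleEigengene(
        values=pd.Series(me, index=expr.sample_ids),
        variance_explained=var_explained,
        module=module,
        n_genes_used=x.shape[0],
    )


def module_de_test(me: ModuleEigengene, groups: pd.Series) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance) of the eigengene.

    ``groups`` must take exactly two levels over the eigengene's
    samples; returns (t, two-sided p).  A zero pooled variance with a
    nonzero mean difference yields t = +/-inf, p = 0.
    """
    groups = groups.reindex(me.sample_ids)
    levels = groups.dropna().unique()
    if len(levels) != 2:
        raise SampleNetworkError("exactly two group levels required")
    a = me.values[groups == levels[0]].to_numpy()
    b = me.values[groups == levels[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise SampleNetworkError("group too small")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def gene_de_table(
    expr: ExpressionMatrix, groups: pd.Series, log2_input: bool = True
) -> pd.DataFrame:
    """Per-gene Student's t-test on log2 values with Benjamini-Hochberg q.

    With ``log2_input=False`` values are log2-transformed first (all
    values must be positive).  Genes with zero variance in both groups
    are flagged ``not testable`` and excluded from the q-value ranking.
    """
    groups = groups.reindex(expr.sample_ids)
    levels = groups.dropna().unique()
    if len(levels) != 2:
        raise SampleNetworkError("exactly two group levels required")
    x = expr.data.to_numpy()
    if not log2_input:
        if (x <= 0).any():
            raise SampleNetworkError("log transform undefined")
        x = np.log2(x)
    m1 = (groups == levels[0]).to_numpy()
    m2 = (groups == levels[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise SampleNetworkError("group too small")
    a, b = x[:, m1], x[:, m2]
    testable = (a.var(axis=1, ddof=1) > 0) | (b.var(axis=1, ddof=1) > 0)
    t = np.full(x.shape[0], np.nan)
    p = np.full(x.shape[0], np.nan)
    if testable.any():
        res = stats.ttest_ind(a[testable], b[testable], axis=1, equal_var=True)
        t[testable] = res.statistic
        p[testable] = res.pvalue
    q = np.full(x.shape[0], np.nan)
    if testable.any():
        q[testable] = multipletests(p[testable], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean1": a.mean(axis=1),
            "mean2": b.mean(axis=1),
            "t": t,
            "p": p,
            "q": q,
            "status": np.where(testable, "ok", "not testable"),
        },
        index=expr.feature_ids,
    )


@dataclass
class ModuleScanTable:
    """Per-module topology comparison and eigengene differential expression."""

    table: pd.DataFrame
    bonferroni_threshold: float
    n_modules: int
    group_levels: tuple

    def significant(self, column: str = "p_diff") -> pd.DataFrame:
        flag = {"p_diff": "sig_diff_bonferroni", "p_DE": "sig_DE_bonferroni"}[column]
        return self.table[self.table[flag].fillna(False)]


def module_scan(
    expr: ExpressionMatrix,
    modules: GeneSetCollection,
    groups: pd.Series,
    corr_method: str = "pearson",
    beta: float = 2.0,
) -> ModuleScanTable:
    """Scan every module for topology differences and eigengene DE.

    For each module, one sample network is built *per group* over the
    module's genes (groups standardized internally), their cor(K,C)
    values compared with the Fisher-z test, and the module eigengene
    (computed over all samples) tested between groups with Student's
    t-test.  Per-module failures are recorded in the row status, never
    aborting the scan.
    """
    groups = groups.reindex(expr.sample_ids)
    levels = list(groups.dropna().unique())
    if len(levels) != 2:
        raise SampleNetworkError("exactly two group levels required")
    ids1 = groups.index[groups == levels[0]]
    ids2 = groups.index[groups == levels[1]]
    if len(ids1) < 4 or len(ids2) < 4:
        raise SampleNetworkError("group too small")

    rows = []
    for name, genes in modules:
        row = {
            "module": name,
            "n_genes": np.nan, "corKC_group1": np.nan, "corKC_group2": np.nan,
            "n1": len(ids1), "n2": len(ids2), "z_diff": np.nan,
            "p_diff": np.nan, "p_DE": np.nan, "status": "ok",
        }
        try:
            matched = [g for g in genes if g in expr.data.index]
            if len(matched) < 2:
                raise SampleNetworkError("no usable genes")
            sub = expr.subset_features(matched)
            rs = []
            for ids in (ids1, ids2):
                adj, corr = build_adjacency(
                    sub.subset_samples(list(ids)),
                    corr_method=corr_method, beta=beta,
                )
                rs.append(network_summary(adj, corr=corr).corKC)
            cmp = compare_corKC(rs[0], len(ids1), rs[1], len(ids2))
            me = module_eigengene(expr, matched, module=name)
            _, p_de = module_de_test(me, groups)
            row.update(
                n_genes=len(matched), corKC_group1=rs[0], corKC_group2=rs[1],
                z_diff=cmp.z_diff, p_diff=cmp.p, p_DE=p_de,
            )
        except SampleNetworkError as exc:
            row["status"] = str(exc)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("module")
    m = len(modules)
    bonf = 0.05 / m
    table["sig_diff_bonferroni"] = table["p_diff"] < bonf
    table["sig_DE_bonferroni"] = table["p_DE"] < bonf
    return ModuleScanTable(
        table=table, bonferroni_threshold=bonf, n_modules=m,
        group_levels=tuple(levels),
    )


def me_regression(me: ModuleEigengene, covariates: TraitTable) -> pd.DataFrame:
    """OLS of the module eigengene on sample covariates.

    Categorical covariates are expanded to indicator contrasts (first
    level as reference).  Returns one row per design-matrix term with
    the coefficient, its t-statistic and two-sided p-value.
    """
    aligned = covariates.aligned_to(me.sample_ids).data
    parts = []
    for cov in aligned.columns:
        col = aligned[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
    design = pd.concat(parts, axis=1)
    design = sm.add_constant(design)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise SampleNetworkError("collinear covariates")
    if len(me.values) <= design.shape[1]:
        raise SampleNetworkError("too few samples for the design")
    fit = sm.OLS(me.values.to_numpy(), design).fit()
    return pd.DataFrame(
        {"coefficient": fit.params, "t": fit.tvalues, "p": fit.pvalues}
    )
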