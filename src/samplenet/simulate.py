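"""Synthetic-data generators for sample-network studies.

Three generator families:

* :func:`simulate_module` — genes with a ladder of correlations around a
  common "seed eigengene", the standard co-expression-module simulator.
  :func:`waterfall_experiment` sweeps its ``min_cor`` and network size to
  map how cor(K,C) responds to density and size.
* :func:`simulate_factorizable` — exactly factorizable adjacencies
  a_ij = CF(i) CF(j), for which cor(K,C) admits a closed-form
  approximation in terms of network heterogeneity.
* :func:`simulate_disease_module` — a 500-gene, 100-subject "disease
  module" in which differential expression of the first principal
  component carries no disease signal while network topology does.

Cohort helpers (:func:`simulate_clean_cohort`,
:func:`simulate_outlier_cohort`) generate sample-level fixtures for
outlier-detection and group-comparison studies.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    SampleAdjacency,
    SampleNetworkError,
    TraitTable,
)
from .network import network_summary, sample_correlation, signed_power_adjacency

__all__ = [
    "ModuleSimSpec",
    "DiseaseModuleSpec",
    "simulate_module",
    "waterfall_experiment",
    "simulate_factorizable",
    "simulate_disease_module",
    "simulate_clean_cohort",
    "simulate_outlier_cohort",
]

_R_MAX = 0.999  # top of the correlation ladder; 1.0 would yield zero-noise genes


@dataclass
class ModuleSimSpec:
    """Parameters of the module simulator.

    ``n_observations`` is the length of the seed eigengene (the number
    of observations each simulated gene has).  Gene j targets a
    correlation with the seed of

        r_j = min_cor + (0.999 - min_cor) * (1 - ((j-1)/(n_genes-1))**cor_power)

    so the ladder runs from ~1 down to ``min_cor``.  With probability
    ``prop_negative`` a gene's sign is flipped.
    """

    n_genes: int
    n_observations: int
    min_cor: float
    cor_power: float = 0.75
    prop_negative: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise SampleNetworkError("too few genes")
        if not (0 < self.min_cor < 1):
            raise SampleNetworkError("min_cor must lie in (0, 1)")
        if self.cor_power <= 0:
            raise SampleNetworkError("cor_power must be positive")
        if not (0 <= self.prop_negative <= 1):
            raise SampleNetworkError("prop_negative must lie in [0, 1]")


@dataclass
class DiseaseModuleSpec:
    """Parameters of the disease-module generator (defaults are the study design).

    Two unrelated sub-modules: 200 signal genes simulated around a seed
    eigengene that defines disease status, and 300 noise genes around an
    independent seed.  100 subjects: the 50 with the highest seed-eigengene
    values are controls, the next 25 moderate, the bottom 25 severe.
    Signal genes receive a per-gene base mean mu_g ~ Normal(2, 2) on the
    control side and (2/3) mu_g on the affected side (disease lowers mean
    expression); noise genes receive per-gene means ~ Normal(2/3, 2/3)
    shared by all subjects.
    """

    n_genes_signal: int = 200
    n_genes_noise: int = 300
    n_control: int = 50
    n_moderate: int = 25
    n_severe: int = 25
    control_mean_loc: float = 2.0
    control_mean_scale: float = 2.0
    noise_mean_loc: float = 2.0 / 3.0
    noise_mean_scale: float = 2.0 / 3.0
    affected_mean_factor: float = 2.0 / 3.0
    signal_min_cor: float = 0.5
    noise_min_cor: float = 0.85
    cor_power: float = 0.75
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.affected_mean_factor < 1):
            raise SampleNetworkError("affected_mean_factor must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_moderate + self.n_severe


def _correlation_ladder(spec: ModuleSimSpec) -> np.ndarray:
    j = np.arange(spec.n_genes, dtype=float)
    frac = j / (spec.n_genes - 1)
    return spec.min_cor + (_R_MAX - spec.min_cor) * (1.0 - frac**spec.cor_power)


def _simulate_module_values(
    spec: ModuleSimSpec, rng: np.random.Generator, seed_vector: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Raw simulator: returns (genes x observations matrix, seed eigengene)."""
    if seed_vector is None:
        seed_vector = rng.standard_normal(spec.n_observations)
    u = (seed_vector - seed_vector.mean()) / seed_vector.std()
    r = _correlation_ladder(spec)
    eps = rng.standard_normal((spec.n_genes, spec.n_observations))
    signs = np.where(
        rng.random(spec.n_genes) < spec.prop_negative, -1.0, 1.0
    )
    x = signs[:, None] * (r[:, None] * u[None, :] + np.sqrt(1 - r**2)[:, None] * eps)
    # standardize each gene (mean 0, sd 1), as the reference simulator does
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    return x, seed_vector


def simulate_module(spec: ModuleSimSpec) -> ExpressionMatrix:
    """Simulate a co-expression module around a random seed eigengene."""
    rng = np.random.default_rng(spec.rng_seed)
    x, _ = _simulate_module_values(spec, rng)
    return ExpressionMatrix.from_arrays(x)


def waterfall_experiment(
    min_cor_grid: np.ndarray | None = None,
    size_grid: np.ndarray | None = None,
    n_observations: int = 5000,
    beta: float = 2.0,
    cor_power: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Map cor(K,C) over module strength (min_cor) and network size.

    For each (min_cor, n_nodes) cell a module of ``n_nodes`` genes is
    simulated; the *genes* are the network nodes, connected by the
    signed power adjacency of their pairwise correlations over
    ``n_observations`` observations.  Default grids: min_cor from 0.95
    down to 0.05 in steps of 0.05, sizes 10 to 100 by 10.

    Returns a tidy DataFrame with columns
    (min_cor, n_nodes, mean_adjacency, heterogeneity, corKC, corKC_p).
    """
    if min_cor_grid is None:
        min_cor_grid = np.round(np.arange(0.95, 0.049, -0.05), 2)
    if size_grid is None:
        size_grid = np.arange(10, 101, 10)
    min_cor_grid = np.asarray(min_cor_grid, dtype=float)
    size_grid = np.asarray(size_grid, dtype=int)
    if min_cor_grid.size == 0 or size_grid.size == 0:
        raise SampleNetworkError("grids must be nonempty")

    rows = []
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(min_cor_grid.size * size_grid.size)
    idx = 0
    for mc in min_cor_grid:
        for n_nodes in size_grid:
            spec = ModuleSimSpec(
                n_genes=int(n_nodes),
                n_observations=n_observations,
                min_cor=float(mc),
                cor_power=cor_power,
                rng_seed=int(cell_seeds[idx] % (2**31)),
            )
            idx += 1
            expr = simulate_module(spec)
            # genes as network nodes: transpose so genes are the "samples"
            gene_net = ExpressionMatrix(expr.data.T)
            corr = sample_correlation(gene_net, method="pearson")
            adj = signed_power_adjacency(corr, beta=beta)
            summ = network_summary(adj, corr=corr)
            rows.append(
                {
                    "min_cor": float(mc),
                    "n_nodes": int(n_nodes),
                    "mean_adjacency": summ.density,
                    "heterogeneity": summ.heterogeneity,
                    "corKC": summ.corKC,
                    "corKC_p": summ.corKC_p,
                }
            )
    return pd.DataFrame(rows)


def simulate_factorizable(cf: np.ndarray) -> SampleAdjacency:
    """Exactly factorizable adjacency a_ij = cf_i * cf_j (diagonal 1)."""
    cf = np.asarray(cf, dtype=float)
    if cf.ndim != 1 or cf.size < 3:
        raise SampleNetworkError("need at least 3 node contributions")
    if (cf < 0).any() or (cf > 1).any():
        raise SampleNetworkError("invalid contribution")
    a = np.outer(cf, cf)
    np.fill_diagonal(a, 1.0)
    ids = [f"n{i + 1}" for i in range(cf.size)]
    return SampleAdjacency(
        a=pd.DataFrame(a, index=ids, columns=ids), beta=None, kind="signed_cor"
    )


def simulate_disease_module(
    spec: DiseaseModuleSpec | None = None, rng_seed: int | None = None
) -> tuple[ExpressionMatrix, TraitTable]:
    """Simulate the disease module: topology signal without eigengene signal.

    Subjects are ranked by the signal sub-module's seed eigengene: the
    top ``n_control`` are controls, the middle ``n_moderate`` moderate,
    the bottom ``n_severe`` severe.  Returns the 500 x 100 expression
    matrix (genes x subjects) and a trait table with the three-level
    ``status`` plus the binary ``affected`` indicator.
    """
    if spec is None:
        spec = DiseaseModuleSpec()
    if rng_seed is not None:
        spec = DiseaseModuleSpec(**{**spec.__dict__, "rng_seed": rng_seed})
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_samples

    sig_spec = ModuleSimSpec(
        n_genes=spec.n_genes_signal,
        n_observations=n,
        min_cor=spec.signal_min_cor,
        cor_power=spec.cor_power,
        rng_seed=0,  # unused; rng passed directly
    )
    signal, seed_me = _simulate_module_values(sig_spec, rng)

    order = np.argsort(-seed_me)  # descending: controls have high seed ME
    status = np.empty(n, dtype=object)
    status[order[: spec.n_control]] = "control"
    status[order[spec.n_control : spec.n_control + spec.n_moderate]] = "moderate"
    status[order[spec.n_control + spec.n_moderate :]] = "severe"
    control_side = status == "control"

    mu_signal = rng.normal(
        spec.control_mean_loc, spec.control_mean_scale, spec.n_genes_signal
    )
    side = np.where(control_side, 1.0, spec.affected_mean_factor)
    signal = signal + mu_signal[:, None] * side[None, :]

    noise_spec = ModuleSimSpec(
        n_genes=spec.n_genes_noise,
        n_observations=n,
        min_cor=spec.noise_min_cor,
        cor_power=spec.cor_power,
        rng_seed=0,
    )
    noise, _ = _simulate_module_values(noise_spec, rng)
    mu_noise = rng.normal(spec.noise_mean_loc, spec.noise_mean_scale, spec.n_genes_noise)
    noise = noise + mu_noise[:, None]

    values = np.vstack([signal, noise])
    feature_ids = [f"sig{i + 1}" for i in range(spec.n_genes_signal)] + [
        f"noise{i + 1}" for i in range(spec.n_genes_noise)
    ]
    sample_ids = [f"subj{j + 1}" for j in range(n)]
    expr = ExpressionMatrix.from_arrays(values, feature_ids, sample_ids)
    traits = TraitTable(
        pd.DataFrame(
            {
                "status": status,
                "affected": np.where(control_side, "no", "yes"),
                "seed_me": seed_me,
            },
            index=sample_ids,
        )
    )
    return expr, traits


def simulate_clean_cohort(
    n_samples: int = 20,
    n_genes: int = 500,
    noise_sd: float = 0.4,
    seed: int = 0,
    profile_sd: float = 1.0,
) -> ExpressionMatrix:
    """Homogeneous cohort: every sample is the same profile plus iid noise.

    With the defaults, inter-sample correlations sit around
    1 / (1 + noise_sd^2) ~ 0.86, typical of a clean expression dataset.
    """
    rng = np.random.default_rng(seed)
    profile = rng.normal(0.0, profile_sd, n_genes)
    values = profile[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_samples))
    return ExpressionMatrix.from_arrays(values)


def simulate_null_group_pair(
    n_per_group: int = 30,
    n_genes: int = 300,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Null pair for topology-comparison calibration studies.

    One cohort of ``2 * n_per_group`` samples is drawn from a single
    shared-profile generator and randomly split into two groups — a
    randomization null under which the two sample networks have equal
    cor(K,C) in distribution.  ``noise_sd = 1`` puts inter-sample
    correlations around 0.5, a moderately clean dataset.
    """
    rng = np.random.default_rng(seed)
    cohort = simulate_clean_cohort(
        n_samples=2 * n_per_group, n_genes=n_genes, noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    ids = np.array(cohort.sample_ids)
    perm = rng.permutation(ids.size)
    g1 = cohort.subset_samples(list(ids[perm[:n_per_group]]))
    g2 = cohort.subset_samples(list(ids[perm[n_per_group:]]))
    return g1, g2


def simulate_outlier_cohort(
    n_samples: int = 20,
    n_genes: int = 500,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> tuple[ExpressionMatrix, str]:
    """Clean cohort plus one planted outlier (its profile independently permuted).

    Returns the cohort and the planted outlier's sample id (the last
    sample).  The permutation destroys the outlier's correlation with
    the shared profile while preserving its marginal distribution.
    """
    rng = np.random.default_rng(seed)
    profile = rng.normal(0.0, 1.0, n_genes)
    values = profile[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_samples))
    values[:, -1] = rng.permutation(values[:, -1])
    expr = ExpressionMatrix.from_arrays(values)
    return expr, expr.sample_ids[-1]
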