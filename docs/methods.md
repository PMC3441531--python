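# Methods

## Sample adjacency

Samples are nodes; the edge weight between samples *i* and *j* is
`a_ij = ((r_ij + 1)/2)^β` with `r_ij` their correlation and β = 2 by default.
The map is monotone, sign-preserving, and lands in [0, 1] as a network
adjacency must. At β = 2 the identity

    a_ij − r_ij = ((1 − r_ij)/2)²

holds exactly, so the adjacency deviates from the correlation by at most 0.04
once all correlations exceed 0.6 — the regime of real between-sample
correlations — which is why the network's density tracks the mean
inter-sample correlation there.

Correlations default to Pearson: the geometric interpretation of the
framework presumes the product-moment estimator, and expression values are
approximately continuous after the usual transforms. Spearman is available
for heavy-tailed data. Missing values are handled pairwise-complete; a pair
with fewer than 3 shared observations is an error, and zero-variance features
are excluded from all pairs and reported. A Euclidean-distance adjacency
(`1 − d_ij / max d`) is provided for applications where absolute levels
matter; it requires complete data. Hard thresholding (`a_ij ≥ τ → 1`) is
offered for studying binary-network behavior, not recommended for QC.

The diagonal is stored as 1 for convenience but is excluded from every sum
(connectivity, density, clustering coefficient, MAR).

## Node and network concepts

Per node: connectivity `k`, scaled connectivity `K = k/kmax`, standardized
connectivity `Z.K`, weighted clustering coefficient `C` (computed as
`diag(B³) / (k² − Σ a²)` for `B` the zero-diagonal adjacency, algebraically
identical to the double-sum definition), its z-score `Z.C`, and the maximum
adjacency ratio `MAR = Σa²/Σa`, which is near 1 when a node's weight
concentrates in strong edges.

Per network: density (mean off-diagonal adjacency / ISA), mean correlation,
heterogeneity = `sqrt(var(k))/mean(k)` using population moments — chosen so
that homogeneity `1/(1+H²)` equals `(Σk)²/(nΣk²)` exactly — centralization
`n/(n−2) · (kmax/(n−1) − density)` and decentralization `1 − centralization`,
following the standard network-concepts framework.

**cor(K,C)** is the Spearman correlation of (k, C) across nodes. Because
Spearman is rank-invariant, `cor(k,C) = cor(K,C) = cor(Z.K, Z.C)` identically,
and scaling all off-diagonal adjacencies by a constant leaves it unchanged;
both identities are enforced by tests to machine precision. Its p-value uses
the t approximation with df = n − 2 (average ranks on ties); an exact
enumeration over all n! pairings is available for n ≤ 10.

For exactly factorizable networks (`a_ij = CF_i · CF_j`) cor(K,C) is a
function of heterogeneity alone, approximately `0.96 − 2.19/(1 + H²)`. The
value is reported unclamped (it is an approximation of a correlation and
equals −1.23 at H = 0). On a grid of factorizable networks with power-law
contribution profiles the empirical cor(K,C) agrees with this prediction in
rank with Spearman 1.0.

### Degenerate inputs

Uniform networks are legal: when K (or C) has zero variance its z-column is
set to 0 and a flag raised, and cor(K,C) is reported as undefined (NaN /
`null` in JSON) rather than an error. A node with fewer than two effective
neighbours has a zero clustering-coefficient denominator; its C is set to 0
and the node flagged. Z-scores use the sample SD (n − 1).

## Outlier removal

Within each group of comparable samples (e.g. per tissue region or batch):
build the β = 2 network, compute Z.K, remove **all** samples with
Z.K < threshold (default −2), rebuild, repeat. Iteration stops when no sample
falls below threshold, after `max_rounds` (default 10), or when removal would
shrink a group below 4 samples (network concepts need n ≥ 3; the downstream
Fisher test needs n ≥ 4). Batch-per-round removal is the default because the
sample that drags the network's standardization with it is rebuilt away in
the next round anyway; one-at-a-time removal (`mode="single"`) is available
for conservative curation. As rounds proceed, density is non-decreasing and
cor(K,C) moves toward −1 in ≥ 90% of simulated cohorts with planted outliers.

Quantile normalization is the classic reference-distribution method: sort
each column, average across columns at each rank, map back by original
ranks; ties receive the mean of their tied reference values. It is
idempotent and makes all column value-multisets identical.

Covariate screening tests each sample covariate against Z.K, Z.C and MAR —
Kruskal–Wallis across levels for categorical covariates, a Spearman test for
numeric ones; constant covariates are reported "not testable" rather than
erroring. Batch *correction* is deliberately minimal: `align_batches` is a
per-batch location–scale alignment, not an empirical-Bayes model, and a
`combat_hook` callable lets users delegate to an external implementation.

## Comparing group topology

Each group's network is built and standardized independently; the groups'
cor(K,C) values `r_1, r_2` are compared with

    z_diff = (atanh r_1 − atanh r_2) / sqrt(1/(n_1−3) + 1/(n_2−3))

against the standard normal, two-sided by default (one-sided options exist).
Values numerically at ±1 are clamped to magnitude 1 − 1e−15 and flagged —
degenerate module networks do occur. The joint C(k)-curve mode (one network,
points labelled by group) and the separate mode (one network per group) are
both reported and can disagree, even in sign; the disagreement itself is
informative about between-group structure.

The Fisher standard error treats cor(K,C) as if it were a correlation of
n independent pairs, which network concepts are not; the test is therefore
asymptotically heuristic. Under a randomization null (one 60-sample cohort
with inter-sample correlations around 0.5, split at random into two groups
of 30) its measured type-I error at α = 0.05 is ≈ 0.08. Calibration degrades
for very small groups (n ≲ 15) and for cohorts so clean that cor(K,C) pins
near −1, where atanh amplifies tiny rank fluctuations — in those regimes
treat p-values as indicative and prefer larger groups.

## Module scan

Modules are supplied as gene sets (GMT or two-column table); no module
discovery is performed. Per module: one sample network per group restricted
to the module's genes, the Fisher comparison of their cor(K,C), plus a
pooled-variance Student t-test of the module eigengene between groups.
Both p-value columns receive Bonferroni flags at `0.05/m` for m scanned
modules. Row-level failures (e.g. no usable genes) are recorded in a status
column and never abort the scan.

The module eigengene is the first right-singular vector of the module's
submatrix after per-gene standardization (mean 0, SD 1) — without it, genes
on large scales dominate the component; this standardization is a modelling
choice, stated here because alternatives (centering only) exist. The sign is
oriented so the eigengene correlates non-negatively with the module's mean
standardized profile (first-entry-nonnegative as the degenerate fallback),
making it deterministic and stable under gene reordering. Per-gene
differential expression uses Student's t on log2 values with
Benjamini–Hochberg q-values; genes constant in both groups are flagged and
excluded from the ranking. BH controls the tail-area FDR — a different
estimand from local false-discovery rates, which this package does not
compute. Eigengene-on-covariates regression is ordinary least squares with
indicator contrasts for categorical covariates; rank-deficient designs are
rejected.

## Simulators

`simulate_module(n_genes, n_observations, min_cor, cor_power=0.75,
prop_negative=0, seed)` draws a standard-normal seed eigengene and gives
gene *j* the target correlation

    r_j = min_cor + (0.999 − min_cor) · (1 − ((j−1)/(n_genes−1))^cor_power)

realized as `r_j·u + sqrt(1−r_j²)·ε`, then standardizes each gene. The
ladder's top is 0.999, not 1, to avoid zero-noise genes. The exact spacing
of the ladder is a design choice; any ladder spanning [min_cor, ≈1]
produces the same qualitative response surface.

The **waterfall experiment** sweeps min_cor 0.95 → 0.05 (step 0.05) and
network size 10 → 100 (step 10), with the simulated *genes* as network
nodes observed over 5,000 observations, and records density and cor(K,C)
per cell. Strong dense modules give cor(K,C) ≈ −1; weak sparse ones ≈ +1,
with a sharp percolation-like transition near min_cor 0.6 at n = 100.

The **disease module** couples 200 "signal" genes simulated around a seed
eigengene with 300 "noise" genes around an independent seed, over 100
subjects. Subjects are ranked by the signal seed: top 50 = control, next
25 = moderate, bottom 25 = severe. Each signal gene receives a base mean
`μ_g ~ Normal(2, 2)` on the control side and `(2/3)·μ_g` on the affected
side (disease lowers mean expression, with one draw per gene shared within
a side); noise genes receive means `~ Normal(2/3, 2/3)` common to all
subjects. The sub-module correlation floors — 0.5 for signal, 0.85 for
noise — are the package's design choice, picked so the noise sub-module
dominates the observed eigengene (which is then unrelated to disease
status) while the control-vs-affected networks still differ topologically.
Both conditions hold jointly in a majority (~55–60%) of replicates; this is
the phenomenon's intrinsic rate under this design, not a tuning failure —
the observed eigengene picks up chance correlation between the two seed
eigengenes in the remaining replicates.

Cohort helpers generate a shared per-gene profile plus iid sample noise:
`noise_sd = 0.4` (inter-sample r ≈ 0.86) models a clean cohort for outlier
studies, `noise_sd = 1.0` (r ≈ 0.5) a moderately clean one for test
calibration. The planted outlier is a sample whose values are independently
permuted — marginal distribution preserved, correlation destroyed.

All generators are deterministic given their seed (same spec + seed →
bitwise-identical output).

### What the simulators do not emulate

Real expression data have heavy-tailed noise, correlated batch structure,
probe-level artifacts and mean–variance coupling, none of which the
Gaussian generators produce. Passing tests demonstrate the algebra, the
procedures and the qualitative phenomena — not that thresholds such as
Z.K < −2 are optimal for any particular platform.

## Problem sizes and numerical tolerances

The shipped tests and the acceptance script use: 50 random networks
(n = 5…50) for the rank-invariance identity; 50 networks (n ≤ 20) against
the brute-force triple-loop clustering oracle at 1e−10; 5 replicates of the
waterfall n = 100 row (19 grid cells, 5,000 observations each); a 20-point
factorizable grid; 100 outlier cohorts; 200 null group-pairs; 50
disease-module replicates. Full suite ≈ 30 s, acceptance script ≈ 30 s on
one CPU. A trend inversion in the waterfall is counted only above a 0.01
rise in cor(K,C), well above the ≤ 5e−4 jitter on the ±1 saturation
plateaus and well below any genuine reversal.

## Known limitations

* The Fisher z test for cor(K,C) differences is heuristic (see above);
  its p-values are best treated comparatively, as in the module scan.
* cor(K,C) depends on network size in non-factorizable networks, so
  cross-study comparisons should match group sizes where possible.
* Hard-thresholded (binary) sample networks lose the weighted framework's
  robustness; they are provided for exploration.
* No probe-level preprocessing, no gene–gene network construction or module
  discovery, no empirical-Bayes batch correction, and no enrichment
  analysis: modules and cleaned matrices are this package's inputs and
  outputs, respectively.
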