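# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design choices behind `osmetnet`.

## Differential expression

Each gene g is fit by ordinary least squares on the two-group design: the
log₂ fold change is the case-minus-control mean difference and s²_g the
pooled within-group variance on d_g = n_case + n_control − 2 degrees of
freedom. Moderation follows the hierarchical model in which
s²_g | σ²_g ~ σ²_g · χ²_{d_g}/d_g and 1/σ²_g ~ χ²_{d₀}/(d₀·s²₀). The prior
(d₀, s²₀) is estimated by moment matching on e_g = log s²_g − ψ(d_g/2) +
log(d_g/2): the excess of the sample variance of e over ψ′(d_g/2) equals
ψ′(d₀/2), inverted by Newton iteration; s²₀ follows from the mean of e. Two
conventions match the reference R implementation of this estimator exactly
(verified in the test suite by running it through `Rscript`):

* when the moment estimate of ψ′(d₀/2) is non-positive, d₀ = ∞ and
  s²₀ = mean(s²_g) (the variances are consistent with one common value);
* the total df of the moderated t reference distribution is capped at the
  pooled residual df across genes, keeping the reference finite at d₀ = ∞.

Posterior variances are s̃²_g = (d₀·s²₀ + d_g·s²_g)/(d₀ + d_g), so they
always lie between s²_g and s²₀. The moderated t is
log₂FC / (s̃_g·√(1/n₁ + 1/n₂)) with two-sided p-values; BH step-up adjusts
for multiplicity. DEG calls use strict inequalities q < 0.05 and
|log₂FC| > 2. Genes with zero residual variance receive a machine-epsilon
variance floor before moderation; a table in which *every* gene has zero
variance carries no variance information and raises an explicit error
rather than producing arbitrary statistics.

## Over-representation analysis

The overlap k between a query of size n and a set of size K within a
universe of N genes is referred to the hypergeometric upper tail P(X ≥ k).
The universe is the expression matrix (standard practice for array data),
not the genome. Sets pass at raw p < 0.05 with k ≥ 1; BH q-values are
reported over all tested sets but not filtered on, mirroring the filter the
screening design prescribes. Up- and down-regulated DEGs are tested as
separate queries. Note the test is conservative under the null because the
hypergeometric is discrete.

## Gene-set variation scores

For gene i with values x_i1..x_in and bandwidth h_i = sd_i/4, the kernel
CDF statistic is z_ij = n⁻¹ Σ_k Φ((x_ij − x_ik)/h_i); constant genes get
z = 0.5. Per sample, genes are ranked by z descending and the rank r is
symmetrized to w = |N/2 − r|^τ with τ = 1. The enrichment score of a set is
the maximum positive deviation plus the minimum negative deviation of the
random walk that steps up by w/Σw at member genes and down by 1/(N − m)
elsewhere. Degenerate corner: if every member sits exactly mid-rank (all
w = 0, only possible for tiny even-length toy lists), the walk falls back
to unit weights so the score stays defined. Sets with fewer than 2 genes on
the matrix are dropped with a warning (a 1-gene walk is defined and allowed
in tests via `min_size=1`). Differential pathway activity reuses the
moderated linear model with sets in the role of genes, retaining q < 0.05.

## PPI network and feature genes

Edges are retained at confidence ≥ 0.7 (the "medium confidence" convention,
boundary inclusive) between DEG endpoints only; unordered duplicates keep
the maximum score; self-loops are dropped. Isolated DEGs are not network
nodes — downstream intersection is over connected network genes. Symbols
are upper-cased before comparison because cross-database tables differ in
case. Feature genes are the three-way intersection of PPI nodes with two
disease-association tables, reported with per-source membership flags.

## Survival screening

Samples split at the median of each gene's expression, ties to the low
group (deterministic and reproducible). Kaplan-Meier product-limit curves
are compared by the standard two-group log-rank test (hypergeometric
variance at each distinct event time, χ² on 1 df). Genes pass at p < 0.05.
Direction is defined by restricted mean survival over the observed window
(up to the latest observed time): "positive" means the high-expression
group survives longer. RMST was chosen over curve-endpoint comparisons
because it totally orders groups even when curves cross. Times are in
months.

## Heat diffusion on the metabolic graph

The scored subgraph contains all non-gene nodes (compounds, reactions,
enzymes, pathways, modules). L is its unnormalized Laplacian, B the
diagonal 0/1 matrix marking pathway nodes, KI = L + B. Because every scored
component is required to contain a pathway node, KI is symmetric positive
definite and the temperature scores T solve KI·T = G uniquely, where G is
the 0/1 indicator of affected compounds. The solve is a dense Cholesky
factorization (graphs at this scale are small); the relative residual is
checked against 1e-10 and components without a pathway node are excluded
from scoring with a warning rather than making the system singular.

Significance is Monte-Carlo: each permutation redraws the affected set
uniformly among compound-type nodes at the observed cardinality, and
p = (1 + #{T_perm ≥ T_obs}) / (n_perm + 1) per node (add-one estimator;
minimum attainable p is 1/(n_perm+1)). Since T is linear in G, permuted
scores are sums of precomputed unit-response columns of KI⁻¹, so the
permutation loop is a cheap matrix slice per draw. Only the ordering of
observed versus permuted scores enters the p-value, so any positive
rescaling of the solve — or a global sign flip with the comparison tail
flipped along with it — leaves every p-value unchanged; the tests assert
both. Default n_perm = 10000 in the pipeline; a seed is mandatory.

Nodes with p < 0.05 (strict) induce the significant subnetwork. Gene nodes
never enter L/B/KI; DEG-compound interaction edges are overlaid only for
compounds that survived retention. Compounds are ranked by descending
DEG-interaction count (ties: smaller p, then lexical id); the top compound
is the key disease-associated metabolite. Module-type nodes get
B(i,i) = 0 — only literal pathway nodes anchor the system.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with planted, exactly
recorded ground truth. All generators are pure functions of the
configuration (seed included) — identical configuration yields
byte-identical outputs.

* **Expression** — log₂-scale values for 19 case and 4 control samples
  (the emulated study's shape) over 1000 genes by default; per-gene base
  means uniform on [4, 12]; the first 40 genes carry exact ±3 log₂
  mean shifts with alternating sign; i.i.d. Gaussian noise, sd 1. These
  defaults give ≈95% recall at ≈5 sd separation in the moderated t — a
  separable but non-trivial calling problem.
* **Survival** — a separate cohort (n = 80) with per-gene expression
  N(8, 2²); exponential event times whose log hazard adds log HR_g for
  each planted gene whose expression exceeds its cohort median; baseline
  hazard 1/60 per month (median overall survival ≈ 3.5 years, typical of
  pediatric osteosarcoma cohorts); default planted hazard ratios 3 and 1/3;
  administrative censoring replaces a Bernoulli(0.3) subset of times by a
  uniform fraction of the event time.
* **Metabolic graph** — 80 compounds, 50 reactions, 15 enzymes, 5 pathways,
  3 modules connected by the compound–reaction / reaction–enzyme /
  reaction–pathway / pathway–module template, all pathways anchored to the
  first module so the scored subgraph is one component. Four affected
  compounds (≈5% of the pool, echoing the few-affected-versus-large-network
  imbalance of real metabolic graphs) attach only to the reactions of the
  first ("hot") pathway.
* **Association tables** — a PPI edge list whose planted-DEG backbone is
  connected with scores in [0.7, 1] plus sub-threshold decoys; two disease
  tables covering 80% of the DE set plus decoys; a compound–gene table
  linking the first affected compound to six DEGs (the planted key
  metabolite) and the others to one each; a name→id mapping table.

Not emulated: probe-level microarray noise, batch effects, gene-gene
correlation, realistic KEGG topology statistics, or informative censoring.
Passing tests therefore demonstrate correctness and calibration of the
algorithms under a clean generative model, not performance on real
accessions — the original study's headline counts depend on database
snapshots and are out of scope.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at desk scale: 50×10 oracle
matrices (20 seeds), exhaustive hypergeometric enumeration to N = 20,
exhaustive GSVA walks to 12 genes, 500-permutation survival nulls,
1000-permutation diffusion nulls over ~150-node graphs, and 50-replicate
power estimates; the full suite completes in well under a minute of compute
per module. Tolerances: 1e-10 absolute for OLS agreement, 1e-6 relative for
the prior solve and kernel quadrature, exact (float-sum) agreement for the
ES walk, 1e-10 relative residual for the diffusion solve. Null-calibration
checks are Kolmogorov–Smirnov tests at fixed seeds; the diffusion check
tracks a single fixed node across independent replicates because node-wise
p-values within one realization are strongly dependent through the shared
observed draw.

## Known limitations

* Only the two-group design is supported (no covariates or array weights).
* ORA ignores gene-set redundancy and ontology topology.
* The GSVA implementation covers the Gaussian-kernel variant with τ = 1 and
  the max-minus-min ES; Poisson-kernel and ssGSEA-style alternatives are
  out of scope.
* The diffusion null redraws the affected set among compounds
  (Monte-Carlo); a parametric normalization is not provided.
* Survival screening is univariate; no Cox adjustment or optimal cut-point
  scanning.
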