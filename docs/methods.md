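# Methods

This note documents the models and procedures implemented in `gmicnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Pipeline model

The pipeline assumes a genes × samples matrix of *already normalized*
log2-scale abundances with complete data. Missing values are rejected rather
than imputed because both the correlation stage and the discretization stage
assume complete rows.

### Gene filtering and outliers

Genes with a zero fraction strictly above `max_zero_fraction` (default 0.9,
i.e. "more than 90% zeros") are dropped; the boundary is strict, so a gene
zero in exactly 90% of samples survives. Outlier samples are flagged by
average-linkage clustering on Euclidean distances of per-gene z-scored
expression: samples falling into clusters smaller than `min_cluster` below a
user cut. The default flags nothing — there is no principled universal cut,
so the dendrogram merge heights are reported and the cut is an explicit user
decision rather than silent data deletion.

### Co-expression network

Biweight midcorrelation downweights deviations from the median by the Tukey
biweight `(1 − u²)²` with `u = (x − median)/(9·MAD)`, making single
outliers nearly irrelevant where Pearson correlation can move by > 0.1.
Vectors with zero MAD fall back to Pearson (logged); zero-variance genes are
excluded from the network with a warning and land in module 0.

The signed-hybrid adjacency keeps positive correlations raised to the soft
power β (default 5) and zeroes negative ones, preserving sign information
while keeping weights in [0, 1]. `pick_soft_threshold` reports the signed
scale-free fit R² and mean connectivity per candidate power for users fitting
new data; the pipeline default follows the established β = 5.

Topological overlap is
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`; clustering
runs on 1 − TOM with average linkage.

**Tree cut.** Modules are defined by a static cut (default height 0.998)
followed by recursive *balanced-branch splitting*: inside a cluster, any
subtree node whose two branches each carry at least `min_module_size` genes
is a block boundary and the branches are split apart. The rationale is
empirical and robust: under average linkage, genes of one homogeneous module
accrete one or a few at a time (chained topology), whereas two distinct
blocks join as two large branches — so balanced internal nodes appear only
at genuine boundaries, and the rule introduces no new threshold. A pure
static cut cannot separate blocks whose factors are correlated at ~0.5–0.6,
because their cross-block merge height sits below any height that still
keeps weakly loading genes attached. Clusters below `min_module_size` become
module 0 (unassigned); modules are renumbered 1..M by decreasing size.

**Eigengenes.** Per module, genes are z-scored and the first right singular
vector over samples is rescaled to unit sample variance (ddof = 1) and
sign-fixed so it correlates non-negatively with the module's mean
standardized expression (exact zero ties resolve toward a positive first
entry). `variance_explained` is σ₁²/Σσ². Modules whose eigengenes are closer
than the merge height (default 0.25 on 1 − cor, strict) are collapsed
iteratively until a fixed point; the module count never increases.

### Signature scoring

The scorer is a transparent single-sample rank-enrichment statistic: per
sample, genes are ranked by expression (average ranks on ties; walk order
ties broken by gene id), weighted by rank^α (α default 0.25), and each gene
set receives the normalized running-sum gap between the weighted hit CDF and
the uniform miss CDF, divided by the gene count, giving a score in (−1, 1)
that depends on within-sample ranks only. Scores are then centered and
scaled per signature across samples. This is a generic surrogate for
compendium-based cell-type scoring: it needs only a GMT of marker sets and
produces per-sample scores with the statistical structure the downstream
network expects. It does not perform deconvolution, calibration, or
spillover correction.

### Discretization

Hartemink's scheme: quantile pre-binning into `ibreaks` levels (default 20),
then per variable (column order) greedy merges of adjacent levels, each step
collapsing the pair whose merge loses the least total pairwise mutual
information with the other variables, until `breaks` levels (default 3)
remain. The greedy step is exact by default, and the implementation can
return a per-merge trace so stepwise optimality is directly assertable.

Two subtleties are documented because they are easy to get wrong. First,
exact ties are resolved by erasing the bin boundary farthest from the ideal
quantile boundaries {i/breaks}, which keeps the binning quantile-like when
merges are genuinely equivalent. Second, for *independent* variables the
empirical mutual information is pure sampling noise of order (r−1)/(2n) per
companion, so the greedy's choices are noise-driven and the final occupancy
is not guaranteed to be balanced; passing `tie_tol > 0` (on the scale of
that noise) treats near-equal losses as ties and recovers balanced quantile
bins. The exact greedy remains the default because it preserved more
dependence signal in planted-recovery benchmarks.

### Structure learning and averaging

The BDeu (Bayesian Dirichlet equivalent uniform) score with imaginary sample
size `iss = 1` is used throughout; it is likelihood-equivalent, so Markov
equivalent DAGs score identically, and a uniform structure prior is assumed.
Family scores are cached by (node, parent set).

Search is hill climbing over arc additions, deletions and reversals with a
tabu memory: when no move improves, the best non-tabu move is applied anyway
(up to 10 consecutive worsening steps, list length 10, iteration budget
10·p²), with aspiration allowing any move that beats the incumbent best. The
search is fully deterministic — moves are scanned in fixed order and strict
improvement is required — and the best structure visited is returned; at
return, no single move improves it.

Bootstrap arc strength draws R (default 500) resamples of the rows with
replacement; replicate r is seeded `base_seed + r`, so partial runs and
parallel splits reproduce exactly. Strength is the fraction of replicates
containing an edge in either orientation; direction is the orientation
frequency among those. The averaged network keeps arcs with strength ≥ a
threshold; the default threshold minimizes the L1 distance between the
empirical CDF of strengths and an ideal two-point distribution on {0, 1}
with 0-mass equal to the fraction of strengths below the candidate, taking
the smallest minimizer. Arcs orient by majority direction (exact ties keep
the lexicographically smaller orientation, logged). If the kept arcs contain
a cycle, the arc with the smallest strength × direction product inside a
strongly connected component is deleted (logged) until the graph is acyclic
— downstream consumers require a DAG and the averaging step itself does not
guarantee one.

### Module naming and gene influence

Modules are named by hypergeometric over-representation against an
annotation GMT (universe = assigned genes by default; ties by smaller p,
then set name). Labels are `<abbrev>-<index>` where the abbreviation takes
each word's conventional biochemical symbol when one is known (e.g.
transferrin → "Tf", giving "TfT-40" for a transferrin-transport set on
module 40) and the capitalized initial otherwise, truncated to six
characters; a user label map overrides. Naming is descriptive, so no
multiple-testing correction is applied to the labels; the enrichment report
additionally emits Benjamini–Hochberg adjusted p-values for inferential use.

Gene-level influence reruns discretize → bootstrap → average on the genes of
selected modules (capped at 200 genes by default — bootstrap structure
learning is the costly step), keeps arcs with strength ≥ 0.04, and ranks
genes by unnormalized directed betweenness centrality (arcs unweighted),
with kTotal from the co-expression adjacency breaking ties. A gene that
drives many others directly has betweenness 0 by construction (it lies on no
shortest path between third parties), which is why the influence view pairs
betweenness with kTotal instead of relying on either alone.

## Synthetic benchmark

The generator plants K latent factors wired in a random DAG (random
topological order, Bernoulli arcs, signed uniform weights) propagated by
linear-Gaussian structural equations with unit innovation noise. Module
genes load on their factor (loadings U(0.6, 1.0)) with Gaussian noise (sd 1);
background genes are pure noise; each cell type's abundance is a noisy
function of a designated factor (effect 0.7 on the standardized factor,
noise sd 0.8) added onto that type's marker genes; everything is shifted to
a nonnegative log2-like scale. Linear-Gaussian equations were chosen because
the implied covariance is closed-form, enabling analytic checks (within-module
correlation ℓᵢℓⱼ/√((ℓᵢ²+σ²)(ℓⱼ²+σ²))).

Deliberate calibration, fixed once: factor-DAG weights are drawn from
U(0.4, 0.7), so DAG-adjacent factors correlate at w/√(1+w²) ∈ [0.37, 0.57] —
strong enough for the network layer to detect at n = 300–400, weak enough
that adjacent factors' modules remain separable; the abundance-factor
correlation is 0.66 by construction, below the 0.75 eigengene-merge
boundary. Because a cell type's whole per-sample abundance is shared by its
markers, marker blocks are genuine co-expression modules and the ground
truth records them as such (modules K+1..K+c).

What passing these tests shows: the implementation recovers block structure,
ranks, and conditional-independence structure it was designed to detect,
at realistic cohort sizes, reproducibly. What it does not show: robustness
to count-level noise (negative binomial read sampling), batch effects,
nonlinear regulation, or compositional artifacts of real bulk RNA-seq —
none of which the generator emulates.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the full pipeline at
500 genes × 400 samples with 100 bootstrap replicates over 8–10 network
nodes, and verify the scoring/search core against brute-force oracles on
instances small enough to enumerate (≤ 3 variables for exhaustive DAG
scoring, ≤ 8 nodes for path enumeration). These sizes were chosen so the
entire suite completes in well under a minute while every stage still
operates in its intended regime; the published default of 500 bootstrap
replicates is retained in `RunConfig` for real analyses.

Tolerances: correlation/TOM oracle agreement at 1e-10–1e-12; BDeu oracle
agreement at 1e-8 over 1000 random instances; eigengene unit variance at
1e-8. Degenerate inputs (zero-variance genes or signatures, modules with no
varying genes, empty annotation) are either skipped with a logged warning or
rejected with a typed error, as documented per function.

## Known limitations

- Single-block co-expression only; memory is O(genes²).
- The tree-cut variant (static cut + balanced-branch splitting) is one
  defensible choice among several; module counts on real cohorts will differ
  from other cut variants, and an adaptive branch-shape cut is a natural
  extension point.
- The averaged network is forced acyclic by a heuristic deletion rule; when
  bootstrap orientations are near 50/50 the chosen orientation carries
  little evidence and should be read as undirected.
- Symbol matching between expression matrices and GMTs is exact (optionally
  case-insensitive); no ortholog mapping.
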