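# Methods

## The agreement score

For a gene *i* and a pair of tissue samples (a, b), two distances are
defined: the **ontology distance** `d_tree(a, b)`, the number of edges on
the unique path between the samples' regions in the rooted region-ontology
tree, and the **expression distance** `|a_i − b_i|`, the absolute
difference of the gene's (log-scale) expression in the two samples.  The
agreement score of the gene is the Spearman rank correlation between the
two distances taken over **all** unordered sample pairs:

    BRO(i) = spearman( d_tree(a,b), |a_i − b_i| )  over all pairs (a,b)

A positive score means samples from ontologically close regions tend to
have similar expression — the gene's spatial pattern follows the
developmental region hierarchy rather than varying freely across regions.
Within-region pairs (`d_tree = 0`) are included.  Ties in either distance
vector are handled with mid-ranks; the n·(n−1)/2 pair vectors are ranked
with a sort-based ranking and the tree-distance ranks are computed once
per dataset and reused for every gene and every permutation.

A second index based on **triplet ranking** is provided as a check: among
random sample triplets (a, b, c) with `d_tree(a,b) < d_tree(a,c)` (tree
ties excluded from the denominator), the fraction also satisfying
`d_expr(a,b) < d_expr(a,c)`.  Chance level is 0.5; its exhaustive version
enumerates all ordered triplets and serves as the oracle for the sampled
estimator.

Because pair observations share samples they are not independent, so no
closed-form p-value for the Spearman statistic is attempted.  Significance
is empirical: each permutation shuffles a gene's expression values across
samples (severing the sample→region link while keeping the value
distribution), and the score is recomputed.  Defaults: 100 permutations
per gene, permuted scores **pooled** across genes into a single null
(matching a single top-1% cutoff for all genes), add-one estimator
`p = (1 + #{null ≥ obs}) / (1 + N_null)` so p is never 0, and
Benjamini–Hochberg FDR across genes with q < 0.01 as the significance
call; the "observed above the null's 99th percentile" rule is reported
separately as `significant_top1pct`.  A coarser region-level shuffle
(permuting region labels of region-mean profiles) is available behind a
flag, as is a per-gene (non-pooled) null.  Zero-variance genes are flagged
`zero_variance` and excluded from the null and the calls, never silently
dropped.

## Ontology handling

The ontology is a single rooted tree; every node is a region and samples
may be annotated to internal nodes, not only leaves.  All edges count 1
(no branch lengths).  Distances go through the lowest common ancestor and
are cached as a region × region matrix (at most a few thousand regions).
`prune_to_regions` restricts the tree to an analysis set (e.g. a coarse
16-region view of a fine multi-hundred-region annotation): each kept node
is re-parented to its nearest kept proper ancestor and distances are
measured **on the pruned tree** by default — a flag-free design choice;
callers wanting full-tree distances simply skip pruning.  Multi-parent
(DAG) ontologies are out of scope.

## Multi-donor combination and trajectories

Two combination modes: *pooled* (one score over all samples of all
donors) and *per_subject_mean* (score each donor separately, average
unweighted).  The per-donor score table is always emitted so cross-donor
stability can be inspected.  Donors with fewer than 2 samples or 2
distinct regions are dropped with a warning.  For age trajectories each
age group's dataset is first restricted to the regions common to all
groups (so scores are comparable), scored separately, and the cross-gene
mean is traced in age order.

## Companion variance analyses

- **ANOVA**: one-way ANOVA of expression on region label, computed within
  each donor (regions must be replicated within the donor) and summarized
  as the mean F across donors; the summary p is the mean of per-donor
  p-values (a Fisher-combination mode exists but is not the default, since
  the averaging summary is the plainer reading of "average score across
  subjects").  BH-FDR across genes.
- **PCA**: genes centered across samples, no unit-variance scaling
  (covariance, not correlation); components from the SVD of the centered
  matrix, signs fixed by making the largest-magnitude gene loading
  positive; explained-variance fractions are the normalized squared
  singular values.
- **Explained sample-variance**: per gene, R² of least-squares fits on
  one-hot region, one-hot donor, and both; the projection uses an SVD
  basis with a relative rank cut of 1e-10 so the rank-deficient one-hot
  designs (columns sum to the intercept) project exactly onto their true
  column space.  Joint R² ≥ each single-factor R² by column-space nesting.
- **Region clustering**: samples averaged per region, then agglomerative
  average-linkage on Euclidean distances between region profiles.  The
  agglomeration is written out directly (regions number in the hundreds,
  so the cubic loop is trivial) because determinism under ties is part of
  the contract: among equal merge distances the pair with the
  lexicographically smallest region-id pair merges first.  Output is
  Newick plus a merge table.

## Gene sets and gene pairs

Set comparisons use the rank-sum (Mann–Whitney/Wilcoxon) test of the
set's scores against all scored genes or the set's complement, one-tailed
by default (the direction of interest is "markers agree more").  The
marker model of a target gene's spatial variability is a least-squares
quadratic fit — each marker enters linearly and squared, no cross-terms,
keeping the design well-posed at moderate sample counts — with R² against
the constant model; rank-deficient designs are fit via pseudoinverse and
flagged.  Cross-dataset combination multiplies the two score tables'
per-gene scores over their gene-universe intersection and ranks
descending, producing a list for external enrichment tools (enrichment
itself is out of scope).

A gene pair's **spatial correlation** is the Spearman correlation of the
two genes' expression across samples within a donor (Pearson by flag; the
estimator choice is a documented open point), summarized by the median
over donors.  The pair's p-value comes from the donor whose rho is
closest to the median, and the signed log-p is `sign(median_rho) ·
(−log10 p)` so stronger anti-correlation is further left.  Pair sets are
compared against a seeded uniform random baseline of gene pairs
(self-pairs and listed pairs excluded) by one-tailed rank-sum.
Developmental trends fit rho against numeric age by least squares with an
F-test against the constant model, BH-corrected across pairs.  Pair-level
agreement is the **minimum** of the two genes' scores (the weaker gene
bounds what the pair can show); a product variant is a one-line change at
the call site.

## The synthetic generator

The generator is a test harness that emulates the statistical shape of
regional atlas data, not any real dataset.  Its signal model is Brownian
diffusion on the region tree: per gene, the root effect is 0 and each
child's latent effect adds an independent Normal(0, σ_tree²) increment
along the edge; a sample's value is

    μ + region_effect + donor_effect + noise,

with one Normal(0, σ_donor²) draw per (gene, donor) and i.i.d.
Normal(0, σ_noise²) per sample.  This is the minimal structure that makes
the score's target quantifiable in closed form:

    E[(x_a − x_b)²] = σ_tree² · d_tree(a,b) + 2σ_noise²  (+ 2σ_donor² across donors),

verified by Monte-Carlo in the tests.  Genes with σ_tree = 0 are exact
nulls and drive the calibration checks.  Parameters and defaults:
σ_tree 1.0 (per-edge SD, same units as log-expression), σ_noise 1.0,
σ_donor 0 unless donor structure is under test (0.3–0.5 in the
recovery runs), baseline 8.0 (a typical log-intensity), samples placed at
leaf regions by default.  For age series each group gets an independent
dataset with σ_tree scaled by the group multiplier and disjoint donors
(cross-sectional design).  For listed gene pairs the two genes' per-edge
increments are drawn from a bivariate normal at the target correlation,
leaving marginals unchanged.

What the generator does **not** emulate: probe-level noise, batch and
array effects, heavy-tailed intensity distributions, spatially uneven
sampling, and region-specific variance differences.  Passing recovery
tests therefore shows the statistics behave correctly under their assumed
signal model, not that real atlas data satisfy that model.

Two quantitative consequences of the Brownian model worth knowing:
the pairwise rank correlation saturates near 0.5 on path-like trees even
with negligible noise (the expression distance at tree distance t is
half-normal with scale ∝ √t, so its spread grows with its mean), and the
PCA spectrum of pure noise is flat only when genes far outnumber samples
(Marchenko–Pastur spread otherwise); the tests pin both behaviors at the
honestly derived values.

## Problem sizes in the checks

The statistical suites run on a 16-leaf depth-2 tree (21 nodes) with
96–192 samples, 30–300 genes and 50 permutations per gene (pooled nulls
of 10⁴ scores); clustering recovery uses a binary depth-4 tree — a binary
agglomerative dendrogram can only match a binary generating topology
exactly — over 20 seeds; pair enumeration is exercised at the full
3702-sample scale, where only the distance stage is needed.  These sizes
make every distributional check (KS uniformity, >90% detection at
signal/noise ≥ 1, Robinson–Foulds 0) reproducible in well under a minute
each on one core.

## Numerical choices

- Spearman = Pearson on mid-ranks; equality with an independent
  brute-force oracle is asserted to 1e-12 on small instances.
- Probe collapse picks the probe maximizing the mean across donor pairs
  of the Spearman correlation between the donors' region-mean profiles
  (regions present in both donors only); ties break to the
  lexicographically smallest probe id; genes whose probes are all flat
  keep their first probe with a warning.
- Missing values are rejected at load; normalization requires positive
  sample means; normalizing twice is a numerical no-op (asserted at
  1e-10).
- All writers use a fixed 6-significant-digit float format and stable
  column order, so identical runs produce byte-identical files; every
  output table carries a `#`-comment provenance header with a config hash
  and the seed.

## Known limitations

- Permutation nulls assume exchangeability of samples under the null;
  correlated within-donor noise makes the sample-level shuffle slightly
  liberal for strongly donor-structured genes (the region-level shuffle
  flag is the conservative alternative).
- The exhaustive triplet oracle is cubic in sample count and intended for
  ≤ ~30 samples.
- The hand-rolled agglomeration is O(n³) in the number of regions —
  fine for ontologies in the hundreds of regions, not for thousands.
- `combine_subjects(mode="per_subject_mean")` reports no pair count
  (pair counts differ per donor).
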