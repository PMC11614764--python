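# Methods

This note documents the models and procedures implemented in
`keystonenet`, the parameter defaults and why they were chosen, what the
synthetic benchmark does and does not demonstrate, and known
limitations.

## Input model

Abundance input is a MetaPhlAn-style merged TSV: one row per taxon keyed
by a pipe-delimited lineage (`k__...|p__...|...|s__...`), one column per
sample, values in estimated mapped reads. Rows are keyed on the
*terminal* rank of the lineage, so a merged table containing every rank
is not double counted. Estimated read counts may be fractional upstream;
they are rounded half-up to integers because the Dirichlet resampling
step operates on counts. Sample de-duplication (one sample per
participant, chosen uniformly at random under a single seed, participants
visited in sorted order) enforces statistical independence when a cohort
contains repeated sampling. The prevalence filter keeps taxa present
(nonzero) in at least `ceil(0.20 × n_samples)` samples — the boundary is
inclusive. Presence/absence Jaccard similarity between samples (mean over
pairs) is reported as a guard that communities are similar enough to
share one correlation network; pairs of entirely empty samples are
defined to have similarity 0.

## SparCC estimation

The estimator is the canonical SparCC algorithm:

* **Posterior fractions.** Each sample's composition is drawn from
  Dirichlet(counts + 1). The +1 pseudocount keeps fractions strictly
  positive (zeros included), at the cost of exact scale invariance; at
  realistic depths the effect on ρ is below 0.02 (tested).
* **Log-ratio variances.** `t_ij = Var(log f_i − log f_j)` across
  samples, sample variance with denominator n−1.
* **Basis solve.** `w` minimizes `Σ_{i<j not excluded} (w_i + w_j −
  t_ij)²`; with no exclusions this reduces to the closed form
  `w_i = (t_i − W)/(D−2)`, `W = Σ t_i / (2(D−1))`. Solutions are floored
  at 1e−12 to keep the correlation formula defined on degenerate data.
  The solve needs D ≥ 4 taxa.
* **Exclusion loop.** After each solve, the unexcluded off-diagonal pair
  with the largest |ρ| is removed from the system if it exceeds the
  exclusion threshold (default 0.1); ties break lexicographically (first
  pair in row-major order). At most `exclude_iterations` (default 20)
  pairs are excluded; excluded pairs still receive a ρ from the final
  solve. Exclusion removes equations, never taxa.
* **Aggregation.** The element-wise median over `iterations` (default
  100) independent Dirichlet rounds; ρ is clipped to [−1, 1], the
  diagonal set to 1.
* **Significance.** Each taxon's counts are shuffled independently across
  samples; ρ is re-estimated per permutation and compared two-sidedly on
  magnitude. p-values use the add-one estimator, so the smallest
  attainable p is 1/(n_permutations+1). Null re-estimation uses reduced
  internal settings (5 Dirichlet rounds, 2 exclusions, configurable):
  the null's spread is dominated by the data shuffle, not the Dirichlet
  noise, so this preserves calibration (verified: empirical
  false-positive rate at α=0.05 on independent communities falls within
  [0.03, 0.07]) while keeping 1000-permutation runs tractable.

All randomness flows from one seed through spawned generator streams, so
subsample runs are reproducible independently of execution order.

## Consensus networks

The dataset is subsampled without replacement (default 1000 runs of 50
samples); prevalence is determined once on the full de-duplicated data
and the taxon set held fixed across runs (taxa absent from a particular
draw are handled by the Dirichlet pseudocount). An edge enters the
consensus iff p ≤ alpha (inclusive, default 0.05) in at least
`ceil(0.20 × n_runs)` runs (inclusive); its weight is the mean ρ over
exactly the significant runs. All prevalent taxa remain as nodes. The
positive subnetwork keeps edges with mean ρ strictly > 0.

## Node features and keystone potential

Feature topology is the unweighted simple graph of all consensus edges
regardless of sign (clustering and community detection use the positive
subnetwork; feature computation does not restrict sign). Definitions:

* relative node degree `ND = degree / n_nodes` (not n−1);
* local transitivity `T` = fraction of neighbor pairs that are adjacent;
  undefined for degree < 2 and flagged;
* betweenness `BC` = unnormalized shortest-path counts with even
  splitting over equal-length paths;
* closeness computed within each node's reachable component (reported
  but excluded from KP to limit feature collinearity).

`KP = ND × T / BC` with two resolutions of silent division-by-zero
cases, both ours: nodes with degree < 2 get KP = 0 (T undefined), and a
zero BC is replaced by half the smallest positive BC in the network
(preserving ranking; if no node has positive BC, all KP are 0). The
keystone cutoff is `median + 5 × MAD` with the *unscaled* MAD (no
1.4826 normal-consistency constant; the factor is configurable), and the
comparison is strict. Absolute KP values depend on these conventions;
rankings are the meaningful output.

Network summaries: Newman weighted modularity of the greedy
(Clauset–Newman–Moore) partition of the positive subnetwork, and
cohesion = vertex connectivity of the largest connected component of the
sign-ignored graph. An edgeless positive network has modularity 0 by
convention and clusters into singletons.

## Correlation patterns

Sign fractions exclude edges with mean ρ exactly 0 (possible after
averaging signed runs). The within/between-genus partition reads genus
from the lineage-encoded node labels. The keystone-to-genus "dampening"
regression pairs each edge from a keystone genus to a non-keystone genus
(one point per edge, even if several keystones hit one genus) with the
mean |ρ| among that genus's species-level within edges, and fits OLS;
slope p-value and adjusted R² are reported. First-neighbor statistics
exclude keystone-incident edges from the |ρ| averages to avoid
self-confounding.

## Transcriptional states

Per-taxon stratified functional rows (`FEATURE|g__X.s__Y`) are parsed;
UNMAPPED/UNGROUPED/UNINTEGRATED ids and unstratified rows are dropped.
Each sample is normalized to copies per million of the taxon's total
attributed transcription; all-zero samples are flagged and excluded.
State discovery: for k = 2..k_max (default 10; silhouette is undefined
at k = 1), k-means with 25 seeded restarts on the unscaled CPM matrix
(Euclidean, matching the silhouette metric — no feature standardization,
keeping the normalization the sole scaling step); the k with the highest
mean silhouette wins, ties to the smallest k. Clusters with fewer than 3
members ("1 or 2 samples") have their samples excluded and the whole
selection repeats from scratch; if fewer than 6 samples remain the taxon
gets an explicit "no stable state model" result.

Feature importance is the Breiman mean decrease in out-of-bag accuracy
of a manually bagged random forest (default 500 trees, sqrt-features
decision trees): per tree, OOB accuracy is compared with OOB accuracy
after permuting one feature's values, and the decrease averaged over
trees. Trees are bagged by hand so OOB membership is explicit and
seedable. The null refits the forest with permuted state labels
(default 100 times, same tree count) and per-feature p-values use the
add-one estimator. A constant feature has importance exactly 0.

## Synthetic benchmark

`simulate_counts` draws latent log-abundances from a multivariate normal
with an explicit correlation matrix (validated positive semi-definite),
exponentiates, censors, closes to fractions and draws multinomial counts
at a log-uniform per-sample depth (5×10⁴–2×10⁵, the scale of
shallow-to-moderate shotgun profiles). Prevalence structure is emulated
by *detection-limit censoring*: a taxon with dropout rate q is zeroed in
the q fraction of samples where its abundance is lowest. This choice is
deliberate: independent random zeroing at any abundance destroys
log-ratio correlation structure outright (measured sign agreement drops
from 0.99 to 0.69), whereas real absence is abundance-dependent.

`default_keystone_scenario` plants 40 taxa: four genus blocks (sizes
10/10/10/9) with within-block latent correlation 0.6, and one
single-species keystone genus coupled at −0.5 to every member of the
first block and 0 elsewhere — a low-degree, clique-adjacent node, not a
hub. Mean log-abundances are drawn N(2, 0.8) and dropout rates
U(0, 0.3) per taxon (keystone: 1.5 and 0.05, keeping it detectable);
recommended size 120 samples.

`simulate_transcription` places k state centroids at pairwise-equal
distances (orthonormalized directions over the informative features,
offset by `separation` × noise scale) with gamma noise, so values are
nonnegative and CPM-normalizable and `separation` means what it says.

### What the benchmark shows — and does not

Passing tests on this benchmark demonstrate: calibration of the
permutation null on independent communities; recovery of strong planted
correlations (latent 0.9 → estimated > 0.5 at n = 200; sign agreement
≥ 0.95 for |latent ρ| ≥ 0.5 at n = 200 under the default scenario);
correctness of the consensus assembly rules; and recovery of planted
transcriptional states. The generator does not emulate phylogenetic
signal, strain-level variation, or realistic depth/prevalence joint
structure.

One documented negative result: under the default scenario at the
scaled-down study size (100 runs × subsample 50 of 120 samples), the
planted keystone does **not** reliably reach the top ranks of KP. The
cause is a small-sample limitation of SparCC itself, not of this
implementation: with oracle exclusions (or the exclusion loop run to
convergence) at n = 2000 the spurious correlations collapse to
|ρ| ≈ 0.02 and the keystone's couplings are recovered cleanly, but at
n = 50–120 the keystone — being anti-correlated with a block that
carries ~25% of the community — retains systematic positive residual
correlations (median ≈ 0.17 per subsample) to members of the other
blocks. These are realized in the fixed dataset, recur across
subsamples, accumulate consensus support, and turn the keystone into a
bridge node (high betweenness, low transitivity). The corresponding
acceptance test states the intended property and is left failing rather
than weakened; the qualitative sign-structure properties (within-genus
edges more positive than average, keystone edges more negative than the
rest) do hold and are tested separately.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced-scale configurations chosen
as this package's standard quick-validation sizes: 20 Dirichlet rounds
and 100 permutations per subsample run, 100 subsample runs, 200
permutations for calibration checks, 100-tree forests with 50–100 label
permutations. The canonical profile (100 rounds, 1000 permutations, 1000
runs) is the library default. Basis variances are floored at 1e−12; ρ is
clipped to [−1, 1]; the Dirichlet pseudocount is fixed at +1. Batched
estimation processes at most 256 matrix systems per linear-algebra call
to bound memory.

## Limitations

Correlation networks conflate interaction with habitat filtering and
other shared drivers; KP conventions (degree/n vs degree/(n−1), scaled
vs unscaled MAD, zero-BC handling) shift absolute values, so only
rankings and cutoff-relative calls should be compared across studies;
SparCC's sparsity assumption degrades when a large fraction of taxon
pairs is truly correlated (see the negative result above); and the
permutation null with reduced internal iterations is a throughput
compromise, exact only in the limit of matched estimator settings.
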