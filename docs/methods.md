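# Methods

This note documents the statistical machinery implemented in coobnet,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish about real data.

## 1. Ensemble network inference

### Input and preprocessing

The estimator consumes a column-normalized relative-abundance matrix
(OTUs × samples).  Upstream, the standard preparation is:

* **global abundance filter** — drop OTUs contributing less than
  `min_frac` (default 5·10⁻⁵, i.e. 0.005%) of the grand total, computed
  before any partitioning;
* **partitioning** — split samples by lake, continent, or diet-within-
  lake, requiring `min_samples` (default 20) per partition; lakes below
  the threshold surface only through their continent's dataset;
  all-zero OTU rows are dropped per partition;
* **occurrence filter** — keep OTUs present in ≥ 31% of samples (60%
  for diet networks, which are built in copresence-only mode); with
  `keep_sum` the filtered rows are collapsed into one composite row so
  that normalization denominators are conserved exactly.  The composite
  is never eligible for edges: it is an accounting device, not a taxon.

Thresholds are applied as ≥; at the resolution of realistic data the
strict/non-strict distinction never matters.

### Measures and polarity alignment

Four association measures are computed for all OTU pairs: Pearson,
Spearman (average ranks on ties), Bray–Curtis dissimilarity, and
symmetrized Kullback–Leibler divergence.  For KL, each row is
renormalized to a probability vector after adding a pseudocount of
`eps_frac` (default 10⁻⁶) of the row mass, spread uniformly over
samples.

The measures live on different scales, so each is mapped monotonically
onto a common aligned scale in [−1, 1] with +1 = strongest copresence:
correlations unchanged, Bray–Curtis `d ↦ 1 − 2d`, KL
`D ↦ 2·exp(−D) − 1`.  The maps are fixed (not data-dependent) so that
aligned scores are comparable across permutation replicates; the edge's
consensus score is their mean.  The aligned value is a ranking and
reporting device — significance rests on permutation, not on the
absolute aligned scale.

### Candidate selection

Per measure, pairs are ranked by aligned score; the top `n_top`
(default 1000) are copresence candidates, the bottom `n_top` exclusion
candidates (the end of the ranking defines the direction, mirroring the
per-measure edge thresholds of ensemble tools).  Correlations
additionally carry a meaningful zero, so a copresence candidate must
have r > 0 and an exclusion candidate r < 0.  When `2·n_top` exceeds
the number of pairs, a pair belongs to the end it sits closer to.  A
pair becomes a candidate edge iff it qualifies in **all four** measures
with the same direction.  Ranking ties break by canonical pair order
(lexicographic), making selection deterministic.

### Significance: permutation, bootstrap, Brown, BH

For each candidate edge (u, v), per measure:

* **Permutation null** (ReBoot-style): one OTU's values are permuted
  across samples and every column is renormalized; because only one row
  changes, the new column sums are `s_j = S_j − u_j + u_{π(j)}` and the
  null score is the measure on `(u_π/s, v/s)`.  The renormalization
  re-imposes compositional closure under the null.  The same
  permutations are shared across measures (needed for Brown's
  covariance).
* **One-sided p**: `(#{null at least as extreme in the edge's
  direction} + 1)/(n_perm + 1)` (default n_perm = 1000; fewer than 20
  is refused).  When the observation exceeds *every* null draw the
  empirical p saturates at its floor, which would make any multiplicity
  correction over thousands of pairs powerless; in that case the p is
  extended below the floor by a generalized-Pareto fit to the
  exceedances over the null's 90th percentile (peaks-over-threshold).
  The GPD extension stays calibrated for skewed nulls where a Gaussian
  tail would be badly anticonservative, and is floored at 10⁻³⁰.
* **Bootstrap stability**: scores are recomputed under resampling of
  samples with replacement (default n_boot = 1000); an edge is
  discarded as unstable when the permutation-null mean consensus lies
  inside the bootstrap 95% percentile interval.
* **Brown's merge**: the four dependent one-sided p-values are combined
  via `X = −2Σ ln pᵢ ≈ c·χ²(k′)` with `E[X] = 2k`,
  `Var(X) = 4k + 2Σ_{i<j} cov(−2 ln pᵢ, −2 ln pⱼ)`; the pairwise
  covariances are estimated from the per-measure null p-value vectors
  (each permutation replicate ranked within its own null), while the
  per-measure variances are held at their theoretical value 4 so that
  zero covariance reduces *exactly* to Fisher's method.  p = 0 inputs
  are clamped to 1/(n_perm+1) with a warning.
* **BH correction**: Benjamini–Hochberg step-up across edges with the
  family size set to the number of OTU pairs examined during selection,
  not the candidate count.  Candidates are the extreme tail of the very
  statistics being tested, so conditioning the correction on the
  selected set cannot control the FDR; with the selection-consistent
  family size the planted-edge benchmark reaches its precision target
  without any per-dataset tuning.  Edges with q < α (default 0.05) and
  a passing stability flag form the network; nodes are exactly the OTUs
  in ≥ 1 retained edge.

Edge identity is canonical throughout the package: the unordered pair
sorted lexicographically plus the sign.  Two edges are "the same"
across networks only if ids **and** sign agree — the conservative
reading for cross-network comparison.

## 2. Topology, comparison, diet mapping

* **Clustering coefficient** is the mean local coefficient (nodes of
  degree < 2 contribute 0); global transitivity is available via flag.
  **Path length** averages over connected node pairs only (networks are
  routinely disconnected).  **Louvain** runs at resolution 1 with 10
  seeded restarts, reporting the best-modularity partition; module
  count and Q come from the same partition.  **Betweenness** is
  normalized by (N−1)(N−2)/2.
* **Jaccard** similarity over sign-aware edge sets; dendrograms are
  complete-linkage agglomerations of 1 − J; Venn regions partition the
  edge union (capped at 6 networks); the **core** is the sign-aware
  intersection with per-edge scores averaged over the input networks.
* The **shared-edge shuffle test** permutes one network's node labels
  among its own nodes — degree sequence and topology are preserved
  exactly — and counts shared sign-aware edges; p is one-sided (≥
  observed) with the +1 correction, matching the directional question
  "more shared than chance".
* **CZM imputation** replaces a zero in sample *j* by
  `δ_j = label/depth_j` (label default 0.65, the standard
  detection-limit fraction) and shrinks nonzero proportions by
  `1 − z_j δ_j`; the **clr** transform then maps to Aitchison geometry.
  **PCA** is a column-centered, unscaled SVD; components are oriented so
  the largest-magnitude loading is positive, making output
  deterministic; Euclidean distances among full-rank scores equal
  Aitchison distances.
* **PERMANOVA** partitions the squared-distance matrix sequentially
  (diet first, species-within-diet second); pseudo-F tests diet against
  the residual.  Permutation is free over samples by default; an
  optional block strategy permutes whole species units instead, for
  the view that species is the exchangeable unit.  Pairwise contrasts
  rerun the test on level pairs with BH across contrasts.
* **ALDEx-style effects**: per Monte-Carlo instance (default 128;
  tests and the pipeline use fewer where noted), each sample's
  composition is drawn from Dirichlet(counts + 0.5) and
  clr-transformed; the per-OTU statistic is the between-diet difference
  of means over the larger within-diet dispersion, where dispersion is
  the median absolute pairwise clr difference within a group (a
  deterministic, label-symmetric choice that makes swapping the group
  labels negate the effect exactly, instance by instance).  The effect
  is the median ratio over instances; Welch t-test p-values are
  averaged over instances (median optional) then BH-corrected across
  OTUs.  Positive effect = more abundant in the second-named diet.
* **Diet node summaries** report the median clr per network node per
  diet; a node is drawn filled when its median clr exceeds 0, i.e. the
  OTU sits above the sample geometric mean (median exactly 0 counts as
  hollow).
* **Layout**: Fruchterman–Reingold layouts are generated for seeds
  1..n_seeds (default 5000; the bundled pipeline config uses 100) and
  fitted to the PCA node coordinates by similarity Procrustes
  (translation + uniform scale + rotation, reflections allowed by
  default); the seed with the smallest residual SS wins, ties to the
  smaller seed, and the returned coordinates are expressed in the
  ordination's frame.  A deterministic seed enumeration replaces
  "random seeds": identical in distribution, reproducible by
  construction.

## 3. The synthetic community generator

Per sample in group *g* with diet *d*:

1. latent log-abundance `z ~ MVN(μ_g + ln(shift_d), Σ)` with
   `Σ_ii = σ²` (σ default 1), `Σ_ij = ±ρ σ²` for planted pairs, 0
   otherwise (positive-definiteness is checked; overlapping planted
   pairs at high ρ are refused with a pointer to reduce ρ or overlap);
2. relative abundances `p = softmax(z)`;
3. counts `~ Multinomial(depth, p)`, `depth ~ log-normal` (median
   50 000, log-sd 0.35, matching amplicon library sizes).

Baselines (per-OTU mean log-abundance) are drawn as
`cap − Exponential(scale)` (defaults cap 2.0, scale 2.5): a
log-series-like rank-abundance curve.  The heavy rare tail plus finite
depth produces zero inflation without a separate dropout mask; the
bounded upper tail keeps any single taxon from dominating the
compositional denominator.  The latter is essential for benchmarking:
when one taxon holds a large share of the community, its latent
fluctuations induce *genuine* positive correlations among all other
relative abundances (the classic closure artifact), which no pairwise
permutation scheme can separate from planted structure.  Group
baselines get a small jitter (sd 0.25) so lakes differ mildly.

Planted-pair members share one baseline, floored at the median
log-abundance: profile-similarity measures cannot register an
association between taxa on wildly different abundance scales, and an
association planted on a taxon too rare ever to be observed is not a
usable ground truth.

The study-shaped default (`SimConfig.study_mimic`) generates 774 OTUs
across nine lakes on two continents with realistic per-lake sample
sizes (277 specimens total; published counts for two of the lakes vary
slightly between summaries, and the larger values are used), diets
only in the lake that carries dietary diversity, 40 planted positive
pairs (10 core across all
lakes) plus 4 exclusions at ρ = 0.8, and 8-fold diet shifts on 30
OTUs.

**What the generator does not emulate**: phylogenetically structured
taxonomy (lineage strings are random), lake-specific presence/absence
of whole clades, time dynamics, and the full sparsity of real gut data
(the study-scale draw is ~12% zeros; real matrices are far sparser
because taxa are regionally absent, not merely rare).  Passing the
benchmark therefore shows the machinery is correct and calibrated under
the stated generative model, not that real cichlid networks are
recoverable at these rates.

## 4. Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` seeds carried
  in configs or function arguments; the pipeline writes a manifest with
  parameters and SHA-256 checksums, and two runs with one config are
  byte-identical.
* Degenerate inputs fail loudly and early: constant rows under
  correlation are excluded from candidacy (NaN), zero-sum samples are
  named in errors, empty networks are legal results but refuse
  topology, all-coincident Procrustes targets are refused.
* Problem sizes in the acceptance script — 3 benchmark seeds, 8 null
  seeds, 200 PERMANOVA null datasets at 199 permutations, 10 effect
  seeds at 64 Monte-Carlo instances — are the package's standard
  smoke-scale; the benchmark conditions themselves (sample sizes, ρ,
  depth, permutation counts) are never reduced, only the number of
  replicate seeds.

## 5. Known limitations

* Mutual exclusions are hard for the four-measure intersection: the
  Bray–Curtis exclusion ranking is saturated by abundance-mismatched
  pairs, so planted negative associations are usually missed (benchmark
  recall is carried by copresences).  Real networks produced by this
  family of methods are likewise overwhelmingly positive.
* With a strongly dominated community (one taxon ≫ 10% of counts),
  closure-induced correlations are real features of the relative data
  and will be reported as edges; that is a property of pairwise
  compositional inference, not of this implementation.
* Brown's approximation is a two-moment fit; with only four highly
  correlated measures the merged p is accurate to the extent the
  χ²-scaling holds, which the benchmark FDR results support but do not
  prove in general.
* The nested PERMANOVA treats species as a fixed nested factor in the
  sum-of-squares partition; the free-permutation default tests the diet
  effect marginally, and the block strategy should be preferred when
  species, not specimens, are the exchangeable units.
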