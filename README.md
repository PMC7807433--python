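# coobnet

Ensemble co-occurrence network analysis for gut-microbiota OTU count
tables, built around the comparative study design of host-associated
16S surveys: infer a signed association network per host group (lake,
continent, diet), compare networks across groups, extract the conserved
"core" associations, and map a categorical host trait (diet) onto a
network through compositional statistics.

It is written for microbial ecologists who have an OTU × sample count
matrix plus per-sample host metadata and want robust pairwise
associations rather than raw correlations, with a fully synthetic
benchmark (planted associations, known diet effects) to validate every
stage.

## The method

**Network inference** follows the ensemble (CoNet-style) recipe.  On a
column-normalized abundance matrix, four association measures are
computed for every OTU pair *(i, j)*: Pearson and Spearman correlation
across samples, Bray–Curtis dissimilarity
*d(u,v) = Σ|uₖ−vₖ| / Σ(uₖ+vₖ)*, and symmetrized Kullback–Leibler
divergence *D = ½[KL(p‖q) + KL(q‖p)]* on row-renormalized profiles.
Each measure is aligned monotonically onto a common copresence scale in
[−1, 1]; candidate edges are the pairs ranked in every measure's top
*n* (copresence) or bottom *n* (mutual exclusion), and the edge score
is the mean aligned value.

Edge significance uses a ReBoot-style scheme: a permutation null that
shuffles one OTU's values and renormalizes the columns (so the
compositional constraint is re-imposed under the null), a bootstrap
over samples whose 95% interval must clear the null mean (stability
screen), one-sided p-values per measure with a generalized-Pareto tail
extension beyond the Monte-Carlo resolution, Brown's method to merge
the four dependent p-values,

&nbsp;&nbsp;*X = −2 Σ ln pᵢ ~ c·χ²(k′)*, &nbsp;
*c = Var(X)/2E[X]*, &nbsp; *k′ = 2E[X]²/Var(X)*,

with the covariances of −2 ln p estimated from the shared permutation
nulls, and Benjamini–Hochberg control at *q* < 0.05 over all examined
pairs.

**Comparison** treats edges as observations: Jaccard similarity of
sign-aware edge sets, hierarchical clustering on 1 − J, Venn region
counts, the sign-aware intersection (core network), and a
topology-preserving node-label-shuffling test for shared-edge excess.
Per-network topology (degree, clustering, path length, density,
Louvain modularity, betweenness) comes from standard graph statistics.

**Diet mapping** works in log-ratio space: count-zero-multiplicative
imputation, the centered log-ratio transform
*clr(x)ᵢ = ln(xᵢ / g(x))*, covariance PCA (Aitchison geometry),
PERMANOVA with species nested in diet, ALDEx-style Dirichlet
Monte-Carlo effect sizes (median between-diet clr difference over the
larger within-diet dispersion) with Welch t-tests, and per-diet median
clr values mapped onto a Fruchterman–Reingold layout Procrustes-matched
to the PCA ordination.

**Synthetic communities** are drawn from a latent log-normal model:
per-sample log-abundances are multivariate normal with planted
correlations ±ρ for chosen pairs and log diet shifts in the mean;
counts are multinomial at a log-normally distributed depth, so closure
and zero inflation arise exactly as in real sequencing data.

## Worked example

```python
import numpy as np
from coobnet import (CoOccurrenceModel, SimConfig, GroupSpec, PlantedPair,
                     generate_community, ground_truth_eval)
from coobnet.simulate import disjoint_pairs

rng = np.random.default_rng(0)
idx = disjoint_pairs(100, 22, rng)
pairs = [PlantedPair(a, b, rho=0.8, positive=(k < 20))
         for k, (a, b) in enumerate(idx)]
config = SimConfig(n_otus=100,
                   groups=[GroupSpec("Tanganyika", "Africa", 100)],
                   planted_pairs=pairs, seed=0)
table, metadata, truth = generate_community(config)

model = CoOccurrenceModel.from_otu_table(table, name="Tanganyika")
result = model.fit(n_perm=1000, n_boot=1000, seed=1)
print(result.summary(seed=1).T.to_string())
score = ground_truth_eval(result.network, truth)
print(f"precision={score.precision:.2f} recall={score.recall:.2f}")
```

prints

```
                      0
dataset      Tanganyika
n_samples           100
n_otus               98
n_nodes              45
n_edges              25
n_edges_pos          22
n_edges_neg           3
mean_degree    1.111111
clustering          0.0
path_length     1.30303
density        0.025253
n_modules            20
modularity       0.9344
precision=0.80 recall=0.91
```

Of 100 OTUs (98 surviving the occurrence filter), 45 engage in 25
significant associations, 22 of them copresences; 20 of the 22 planted
pairs are recovered and 80% of reported edges are planted ones.  The
`result.candidate_table()` DataFrame holds the per-edge evidence (four
scores, four permutation p-values, merged p, q, stability), and
`result.network` can be written to GraphML or a TSV edge list.

The same workflow is scriptable from the shell:

```
coobnet simulate --out data/            # study-shaped synthetic data
coobnet preprocess --otu data/otu_table.tsv --meta data/metadata.tsv --out prep/
coobnet infer --matrix prep/Tanganyika.norm.tsv --out tanganyika.graphml --seed 1
coobnet compare --nets a.graphml --nets b.graphml --out cmp/
coobnet run --config pipeline.yaml --out results/   # everything at once
```

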