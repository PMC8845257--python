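# ecomorph

Discovery of ecomorphs — groups of species whose morphology converged
under shared microhabitat demands — from three inputs: a species ×
linear-measurement table (CSV, mm), a species × binary
microhabitat-descriptor table (CSV, 0/1), and a rooted Newick tree.

The pipeline:

1. **Measurements** — reduce 70 raw measurements to 36 analysis
   variables (serial leg parts summed, metasoma heights/widths and
   left/right pedipalps averaged), log-transform, compute an isometric
   body size (IsoSize) by projection onto the unit isometric vector, and
   take per-variable OLS residuals on IsoSize as size-corrected traits.
2. **Ecospace** — binary Jaccard distances between species, principal
   coordinates analysis (Gower double-centering), Gaussian-mixture BIC
   curves over candidate cluster counts with first-plateau selection,
   k-means clustering in ordination space, and descriptor-to-cluster
   affiliation tables (Pearson/Spearman).
3. **Phylogenetic statistics** — branch lengths by Grafen's method when
   absent, Brownian-motion covariance, phylogenetic two-block PLS
   between ecology and morphology with a row-permutation test, GLS
   MANOVA of eco-projected morphology across clusters with randomized
   residual permutation, pairwise LS-mean distance tests, and
   Kappa-statistic phylogenetic signal (univariate and multivariate).
4. **Synthetic data** — Yule trees, clustered Bernoulli ecologies, and
   size + Brownian-motion + cluster-shift morphologies, so every stage
   is testable without external data.

## CLI

```sh
# generate a synthetic dataset
ecomorph simulate --seed 7 --out-dir data/

# full analysis from a JSON config
ecomorph run --config cfg.json

# individual stages
ecomorph measure  --raw traits.csv --schema schema.json --out corrected.csv
ecomorph ecospace --habitat habitat.csv --kmax 9 --eps 0.05 --seed 1 --out-dir out/
ecomorph pls      --traits corrected.csv --ecology pcoa_scores.csv --tree tree.nwk --nperm 10000 --seed 1 --out pls.json
ecomorph manova   --traits corrected.csv --groups clusters.csv --tree tree.nwk --nperm 10000 --seed 1 --out manova.json
ecomorph signal   --traits corrected.csv --tree tree.nwk --nperm 10000 --seed 1 --out signal.json
```

A pipeline config is a JSON file mirroring the CLI flags:

```json
{
  "traits": "data/traits.csv",
  "habitat": "data/habitat.csv",
  "tree": "data/tree.nwk",
  "out_dir": "out",
  "traits_stage": "log",
  "kmax": 9,
  "plateau_eps": 0.05,
  "n_perm": 10000,
  "seed": 20220214
}
```

`ecomorph run` writes every intermediate table (distances, PCoA scores,
BIC curve, cluster assignments, affiliation, corrected traits, PLS
loadings) plus `report.json`; re-running the same config reproduces the
report byte for byte.

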