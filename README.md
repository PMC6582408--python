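# csnet — cell-specific gene association networks

Bulk co-expression networks average gene–gene relationships over all
samples, and ordinary single-cell pipelines compare cells only through
their expression vectors.  `csnet` takes the third view: it builds one
**cell-specific network (CSN)** per cell — an undirected boolean
gene–gene graph that records which pairs of genes are statistically
associated *in that particular cell* — and turns the stack of networks
into a **network degree matrix (NDM)** that any expression-style pipeline
(clustering, embedding, pseudotime) can consume unchanged.  It is aimed
at single-cell RNA-seq analysts (it applies equally to large bulk
cohorts) who want to cluster cells by their wiring rather than their
expression, find hub genes per cell type, and detect *dark genes* —
genes that do not change in expression between groups but do change in
network degree.

## The statistic

For genes *x*, *y* and focal cell *k*, draw a neighborhood box around
x_k in the x-direction and around y_k in the y-direction of the pair's
scatter diagram, each targeting a fraction (default 0.1) of the *n*
cells; count the box occupancies n_x, n_y and the occupancy n_xy of
their intersection.  The plug-in local-independence statistic is

    rho_xy^(k) = n_xy/n − (n_x/n)(n_y/n),

with null moments

    mu = 0,   sigma = sqrt( n_x n_y (n − n_x)(n − n_y) / (n^4 (n − 1)) ).

The counts entering these formulas are taken over the *n − 1 non-focal*
cells, under which the null law of n_xy is exactly
Hypergeometric(n−1, n_x, n_y) and the moments above are exact (see
`docs/methods.md`).  The normalized statistic
rho_hat = (rho − mu)/sigma is approximately standard normal under
independence; an edge is declared when rho_hat exceeds the upper-alpha
normal quantile (one-sided, default alpha = 0.01).  Cells where either
gene reads zero get no edge for that pair by default (scRNA-seq zeros
are mostly dropouts).  The NDM entry for gene *x* and cell *k* is the
degree of *x* in cell *k*'s network; columns are then rescaled to a
common total degree.

## Worked example

Two synthetic cell types whose per-gene expression distributions are
identical, but each type has its own module of 8 tightly co-regulated
genes:

```python
from csnet import (PopulationSpec, generate_population, build_all_networks,
                   normalize_ndm, dark_genes, hub_genes, cluster_cells,
                   clustering_scores)

gem, labels, truth = generate_population(PopulationSpec(seed=0))
ndm = normalize_ndm(build_all_networks(gem, sink="degree_only"))

print(hub_genes(ndm, labels, top_k=3))
audit = dark_genes(gem, ndm, labels)
print(sorted(set(audit.loc[audit.dark, "unit_id"])))
for name, mat in (("GEM", gem), ("NDM", ndm)):
    pred = cluster_cells(mat, 2, method="kmeans", seed=0)
    print(name, clustering_scores(pred, labels).ari)
```

prints

```
{'type0': ['g0004', 'g0006', 'g0003'], 'type1': ['g0012', 'g0010', 'g0013']}
['g0000', 'g0001', ..., 'g0015']            # all 16 planted module genes
GEM ARI = 0.007
NDM ARI = 0.638
```

The hub genes of each type are its module genes; all 16 planted genes
are recovered as dark (significant in degree, null in expression); and
k-means with identical parameters separates the types from the NDM but
not from the expression matrix, because the types differ only in their
association structure.

The same workflow is available from the shell:

```sh
csn simulate --n-types 2 --out fixtures/
csn build   --input fixtures/gem.tsv --out run/ --min-cells 1 --no-log1p
csn analyze --input fixtures/gem.tsv --labels fixtures/labels.tsv \
            --out run/ --min-cells 1 --no-log1p
```

`csn build` writes `ndm_raw.tsv`, `ndm.tsv` (normalized) and a
`manifest.json` recording parameters and the input hash.

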