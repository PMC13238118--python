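# scgale

Geometry-aware graph attention learning and explanation for single-cell
count matrices (scRNA-seq gene expression, scATAC-seq peaks, or fixed
genomic windows).

## The problem

Single-cell experiments produce a cells × features count matrix whose rows
are believed to lie near a low-dimensional manifold shaped by gene
regulation. Standard analysis embeds the cells linearly (PCA), clusters
them, and ranks marker features by differential analysis — which finds
features that *differ* between groups, but not necessarily the features the
groups *depend on*. `scgale` takes the complementary, model-based route:

1. **Embed** the matrix with a geometry-regularised autoencoder (GRAE). A
   diffusion-based manifold embedding Ξ (PHATE-style: adaptive α-decay
   kernel → diffusion operator P → potential −log Pᵗ → metric MDS) is
   computed first, and the autoencoder minimises

   L = MSE(X, f⁻¹(f(X))) + λ · (1/N) Σᵢ ‖ξᵢ − f(xᵢ)‖²,

   so the latent space f(X) keeps both the local and global structure of
   the data while remaining decodable.
2. **Build** the k-NN cell–cell graph (k = 15, Euclidean, union-symmetrised)
   in that latent space.
3. **Classify** cells into their annotated types with a two-layer graph
   attention network (GAT): α_ij = softmax_j(aᵀ LeakyReLU(Θ_s xᵢ + Θ_t xⱼ)),
   x′ᵢ = Σⱼ α_ij Θ_t xⱼ. A GCN baseline is included.
4. **Explain** the trained classifier with learned feature and edge masks
   (GNNExplainer-style mutual-information objective): per cell type, the
   mean feature mask yields a ranked importance list and a top-50 feature
   set, which can be compared against Wilcoxon differential features.

All neural components (autoencoders, GAT/GCN, the mask explainer) run on a
small built-in numpy reverse-mode autodiff engine — no deep-learning
framework is required.

A seeded synthetic-data module generates count matrices with planted cell
types, planted markers (negative-binomial noise, Var = μ + μ²/θ), dropout,
and branching pseudotime trajectories, so the full pipeline is testable
without any download.

## Worked example

```python
import scgale as sg

# 600 cells, 4 types, 20 planted markers each (4-fold NB mean shift)
spec = sg.SyntheticSpec(n_cells=600, n_features=500, seed=8)
m, truth = sg.generate_counts(spec)
ml = sg.log_transform(sg.normalize_library_size(m))

xi = sg.phate_embed(ml, params=sg.GeometryParams(seed=0))
grae = sg.train_grae(ml, xi, sg.TrainConfig(seed=0))
graph = sg.knn_graph(grae.latent, k=15)
clf, report = sg.train_classifier(graph, ml, sg.GATConfig(seed=0))
print(f"macro-F1 {report.f1:.3f}  homogeneity "
      f"{sg.homogeneity(graph, ml.labels):.3f}")

exps = sg.explain_class(clf, graph, ml.counts, ml.labels,
                        sg.ExplainerConfig(seed=0), n_top=50,
                        feature_ids=ml.feature_ids, subsample_cap=5)
top = set(exps["type_0"].top_set(50))
markers = {f"feat_{j}" for j in truth.marker_sets[0]}
print(f"markers recovered in top-50: {len(top & markers)}/20")
```

Output:

```
macro-F1 0.933  homogeneity 0.977
markers recovered in top-50: 20/20
```

The macro-F1 is the test-split score of the GAT on the planted-type labels;
homogeneity (1 − mean fraction of distinct neighbour types per cell,
normalised by k·C) measures how biologically coherent the latent-space
graph is; the recovery count shows the explainer ranks every planted marker
of the class inside its top-50 set.

The same pipeline is available from the shell:

```bash
scgale simulate --outdir sim --n-cells 600 --n-features 500 --seed 8
scgale run-all --input sim/simulated --format mtx --outdir run --no-qc
```

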