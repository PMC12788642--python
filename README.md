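# igtdx

Tabular-to-image conversion with non-Euclidean feature distances, for
CNN classification of high-dimensional numeric tables.

Many strong deep-learning architectures expect images, while most
biomedical data — bulk and single-cell expression matrices, proteomic
and mass-spectrometry profiles — arrives as a samples × features table
with no spatial structure.  `igtdx` bridges the two: it assigns every
feature of a table to one pixel of an `Nr × Nc` grid so that features
that are *similar* end up *close*, then renders each sample's values as
a grayscale pseudo-image a small CNN can classify.  It is aimed at
practitioners with wide, small-n tables (genes ≫ samples) who want to
try convolutional models without hand-crafting a feature arrangement.

## The method

Let `R` be the p×p matrix of ascending ranks of pairwise *feature*
distances and `Q` the rank matrix of Euclidean *pixel* distances on the
row-major grid (`Nr·Nc = p`).  The layout minimizes

```
err(R, Q) = Σ_{i>j} (r_ij − q_ij)²
```

by greedy feature swaps (synchronized row/column transpositions of `R`),
each scored by an exact O(p) incremental update.  Feature similarity can
be measured with any of six metrics, chosen to match the structure you
believe is in the data:

| name | definition | suited to |
|------|------------|-----------|
| `ED` | Euclidean distance | flat, isotropic feature spaces |
| `RD` | 1 − Pearson ρ | linear co-expression structure |
| `GD` | kNN-graph shortest paths (ISOMAP-style) | nonlinear manifolds |
| `JD` | Jensen-Shannon divergence of feature PMFs (base-2, in [0,1]) | compositional / probability-like features |
| `WD` | 1-D Wasserstein-2 via sorted columns | distributional (quantile) differences |
| `TD` | max_k(x_ki−x_kj) − min_k(x_ki−x_kj) (tropical / max-plus) | segment/dominance structure, shift-invariant |

Pixel distances stay Euclidean regardless of the feature metric — the
image grid is a Euclidean space; the optimizer maps non-Euclidean
feature geometry onto it.

The package also ships the six matching synthetic generators (each
planting the structure one metric is designed to see), a compact
NumPy implementation of the reference two-block CNN (3×3 convs, batch
norm, 2×2 pooling, dropout, Adam, LR reduction + early stopping), and a
repeated stratified k-fold evaluation harness reporting accuracy,
precision, recall and F1 as "mean (sd)".

## Worked example

```python
from igtdx import CNNSpec, SimSpec, convert, cross_validate, simulate

ds = simulate(SimSpec(model_name="js", n=120, p=400, seed=0))
layout, images = convert(ds, metric="ED", grid_shape=(20, 20), max_steps=1000, seed=0)
print(f"layout err: {layout.error_trace[0]} -> {layout.error_trace[-1]}")

report = cross_validate(images, CNNSpec(), folds=5, repeats=1, seed=0)
for name in ("accuracy", "precision", "recall", "f1"):
    print(f"{name:10s} {report.cell(name)}")
```

prints (exactly, for this seed):

```
layout err: 101334096428090 -> 47680193225874
accuracy   1.0000 (0.0000)
precision  1.0000 (0.0000)
recall     1.0000 (0.0000)
f1         1.0000 (0.0000)
```

The first line is the rank-mismatch objective before and after
optimization — the drop means similar features were pulled onto nearby
pixels.  The table lines are cross-validated validation indices, fold
mean with population standard deviation: the two Dirichlet classes of
the `js` generator are cleanly separable, so the CNN classifies the
pseudo-images perfectly.  More examples live in `examples/` (one short
script per capability) and the same operations are available from a
thin CLI:

```sh
igtdx simulate --model tropical --n 200 --p 900 --seed 1 data.csv
igtdx convert --metric TD --rows 30 --cols 30 --seed 1 data.csv out/
igtdx evaluate --folds 10 out/images.npz report.json
```

Any CSV/TSV with a binary label column works with `igtdx convert`; the
simulators are just a built-in data source.

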