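# embedconf

Sample-level confidence scores for 2-D embeddings of scRNA-seq data, and
their use for confidence-filtered clustering.

t-SNE is the workhorse for visualizing single-cell RNA-seq datasets, but it
misplaces some cells: a sample can land inside the wrong cell-type cluster
and mislead every downstream interpretation.  `embedconf` quantifies this
per cell and puts the quantity to work:

1. **Ground truth.** With K = 20, the confidence of cell *i* is the fraction
   of its K embedding-space nearest neighbors sharing its label; *i* is
   *erroneously embedded* when fewer than K/2 agree.
2. **Prediction.** A random-forest regressor learns confidence from
   label-free features: each of seven distance measures (Bray-Curtis,
   correlation, cosine, Dice, Kullback-Leibler, Pearson, Whittaker's index)
   evaluated from the cell to its K embedding neighbors in both the
   embedding and the original expression space — 7 x 2 x 20 = 280 features.
   A registry of 28 measures supports screening any single measure.
3. **Baseline.** The neighborhood preservation ratio,
   NPR(i) = |N_original(i) ∩ N_embedding(i)| / K.
4. **Downstream.** Before K-means/DBSCAN clustering (on 30 PCA components),
   the lowest-confidence fraction of cells is removed; after clustering the
   removed cells are assigned to the nearest cluster centers.  Quality is
   scored with ARI, NMI and Hungarian-matched accuracy under three
   conditions: whole data, confident-only, and reassigned.

Intended users: computational biologists who want to flag unreliable
regions of an embedding before interpreting or clustering it, and anyone
benchmarking embedding-quality metrics.

## Worked example

```python
import embedconf as ec

# a synthetic dataset with known embedding errors: 1000 cells, 200 genes,
# 5 classes, 10% of cells' t-SNE coordinates swapped across classes
fx = ec.default_regression_fixture(seed=1)
norm = ec.cpm_log_normalize(fx.counts)

gt = ec.ground_truth_confidence(ec.knn_index(fx.embedding.coords, 20), fx.labels)
print(int(gt.erroneous.sum()))          # 108  <- 100 injected + 8 natural

feats = ec.extract_features(norm, fx.embedding, K=20)
split = ec.train_test_split(1000, 0.2, seed=1)
model = ec.train(feats.rows(split.train_indices), gt.scores[split.train_indices],
                 cv_folds=3, grid={"n_estimators": [100, 300],
                                   "max_depth": [None, 10]}, seed=1)
pred = ec.predict(model, feats)

report = ec.evaluate_detection(pred, gt.erroneous, cutoffs=[100, 50, 10])
print(report.detected, report.total_erroneous)   # [100, 50, 10] 108
```

The detection report reads: among the 100/50/10 cells with the lowest
predicted confidence, 100/50/10 are truly erroneously embedded — a random
scorer would catch about 11/5/1.  On the same fixture the held-out Spearman
correlation between predicted and ground-truth confidence is about 0.77,
and the NPR baseline catches 94 of the lowest-100.

The same flow is available from the shell:

```bash
embedconf simulate --n 1000 --genes 200 --classes 5 --error-fraction 0.1 \
    --seed 1 --outdir fixtures/
embedconf score-gt --embedding fixtures/embedding.tsv \
    --labels fixtures/labels.csv --k 20 --out gt.csv
embedconf run --counts fixtures/counts.csv --labels fixtures/labels.csv \
    --seed 1 --outdir results/
```

`embedconf measures --list` prints the 28-measure registry;
`docs/methods.md` documents the model, conventions and limitations.

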