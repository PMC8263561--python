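# knngap

Rare cell type detection from single-cell RNA-seq count matrices via
k-nearest-neighbour distance-gap statistics.

A tight cluster of `n` cells sitting at a distance from the bulk produces an
abrupt jump in every member's sorted neighbour-distance curve exactly at
neighbour index `n`. `knngap` differences each cell's distance curve twice,
smooths the second difference with the nearest neighbour's values, and scans
candidate cluster sizes `k`: at each `k` the distribution of smoothed values —
Tukey-fenced and augmented with the averaged value of the hypothetical rare
group — is summarised by its skewness. Sizes with skewness above a threshold
(default 2) nominate the top cell and its `k − 1` nearest neighbours; a size
is confirmed only when exactly `k` cells end up carrying it.

The package also ships a gamma-Poisson count simulator with group-wise
differential-expression factors and logistic dropout (a minimal groups-mode
reimplementation of the Splat model), plus evaluation metrics (F1,
sensitivity/specificity, rank AUC, Wilcoxon rank-sum DE testing with
Benjamini–Hochberg correction).

## Library use

```python
import knngap as kg

# simulate a 1003-cell dataset with a planted rare group of 5 cells
params = kg.SimParams(n_genes=5000, group_sizes=(120, 540, 540), de_prob=0.6, seed=1)
data = kg.plant_rare_group(params, rare_size=5, major_sizes=[500, 500])

result = kg.detect(data.counts, kg.RunConfig(seed=1))
for cluster in result.clusters:
    print(cluster.size_k, cluster.skewness_value, cluster.member_cells)
```

The pipeline is: gene/cell filtering → global median normalisation +
log2(x+1) → variance-stabilised feature selection (lowess mean–variance
trend, elbow cut) → PCA (50 components) → exact kNN (euclidean or
manhattan) → gap statistics → skewness curve → assignment. Every stage is
available as a standalone function (`filter_counts`, `median_normalize`,
`vst_select_features`, `pca_embed`, `knn_search`, `gap_profile`,
`build_skewness_curve`, `assign_rare_cells`, ...).

`run_iterative` repeats detection with confirmed rare cells removed, which
uncovers same-size rare clusters shadowed by a larger-gap cluster.

## CLI

```sh
# write a simulated dataset (Matrix Market + labels)
knngap simulate -o sim/ --n-genes 5000 --group-sizes 120,540,540 \
    --de-prob 0.6 --rare-size 5 --majors 500,500 --seed 1

# detect rare cells (reads 10x-style mtx directories or dense TSV/CSV)
knngap run -i sim/ -o out/ --seed 1

# score predictions against ground truth
knngap evaluate --pred out/cells.tsv --truth sim/labels.tsv -o metrics.json

# iterative mode
knngap iterate -i sim/ -o out_iter/ --rounds 3
```

`run` writes `cells.tsv` (cell_id, label, score), `clusters.json` (confirmed
clusters with sizes and skewness) and `config.json` (the resolved settings).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: algebraic and
step-by-step oracles for the statistics, exact-kNN brute-force agreement,
planted-cluster recovery (F1 = 1 across differential-expression levels and
rare sizes 3–20), doublet (size-2) recovery, null specificity on homogeneous
data, the AUC response to the number of informative genes, and a
20,000-cell scalability smoke test. The full suite takes roughly 10–20
minutes on one CPU; everything else finishes in well under a minute.

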