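# hfsof

Hierarchical feature selection and optimization pipeline for multi-class
image diagnosis, built around four stages:

1. **Kernel PCA** (RBF, γ = 1/d) — nonlinear embedding of standardized,
   flattened grayscale images (or any numeric feature table), with
   out-of-sample projection of the held-out split.
2. **Filter ensemble** — information gain, chi-square and symmetrical
   uncertainty computed from shared equal-width-bin contingency tables,
   converted to average-tie ranks and fused by the per-feature median
   (mean fusion and single-filter modes available as ablations).
3. **Scatter-difference thresholding** — per-feature between-class minus
   within-class scatter; features at or above the (1−α) quantile survive.
4. **Wrapper optimization** — whale-migration search (or a PSO baseline)
   over binary feature masks, maximizing 3-fold cross-validated macro-F1 of
   an RBF SVM (C = 100, γ = 0.01), with memoized fitness and fixed folds.

The final subset feeds a one-vs-rest SVM whose report covers the confusion
matrix, per-class precision/recall/F1/AUC, and macro/weighted aggregates.

A synthetic-data module generates ultrasound-like speckled phantom images
and planted-feature tables so the full pipeline is testable offline.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (the heavier
wrapper-vs-exhaustive-oracle checks take a few minutes single-threaded).

## CLI

```sh
# synthesize inputs
hfsof simulate phantoms --out data/phantoms --classes 6 --scale 0.1 --seed 1
hfsof simulate features --out data/table.csv --samples 300 --features 50 --seed 1

# run the full pipeline from a YAML config
hfsof run --config cfg.yaml

# ablation grid (filter_mode x alpha x optimizer)
hfsof ablate --config cfg.yaml --grid grid.yaml --out ablation.tsv

# re-run a recorded pipeline and score a new feature table
hfsof evaluate --model runs/out --data data/new_table.csv
```

Example `cfg.yaml` (all keys optional; defaults shown):

```yaml
input: {path: data/phantoms, type: images, image_size: [64, 64]}
split: {test_fraction: 0.3}
kpca: {p: 1000, gamma: "1/d", mode: rbf}      # mode: skip bypasses KPCA
filters: {bins: 10, mode: fusion_median, pool_size: null}
msdlda: {alpha: 0.05}
optimizer: {name: wma, pop_size: 45, iterations: 100}
svm: {C: 100, gamma: 0.01}
fitness: {k_fold: 3}
seed: 0
output: {dir: runs/out}
```

Example `grid.yaml`:

```yaml
filter_mode: [fusion_median, fusion_mean, ig_only, cs_only, su_only]
alpha: [0.01, 0.05, 0.1]
optimizer: [wma, pso]
```

Each run writes `manifest.json` (resolved config, seeds, per-stage feature
counts, selected indices), per-phase metrics JSON, the rank and scatter
tables, the optimizer trace, and the confusion matrix — all as plain text.
Runs are bit-for-bit reproducible from the single master seed, which fans
out to the split, fold and optimizer seeds.

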