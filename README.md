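# hdnn

Neural-backed decision trees for classifying precursor-miRNA hairpins in
extremely class-imbalanced feature tables.

## The problem

Genome-wide scans for microRNA precursors produce tables with one row per
candidate hairpin — ~29 numeric descriptors each — in which true pre-miRNAs
are outnumbered by pseudo-hairpins at ratios up to 1:5000. At that imbalance
a classifier that answers "negative" for everything scores 99.98% accuracy
while finding nothing, so both the model and the metrics have to be built
for the minority class.

## The model

The H-DNN (hybrid deep neural network) is a binary decision tree whose every
internal node embeds a small dense network:

* each node's network maps a feature vector x through ReLU layers
  (default widths 512-256-64-32-16, dropout after the 256- and 16-unit
  layers) to two output scores y = W·h + b, and routes the sample by
  argmax(y) — class-0 scores go left, class-1 right;
* a candidate split is scored by the weighted Gini impurity
  (n_L/n)·G(L) + (n_R/n)·G(R) with G = 1 − Σ_j p_j², and kept only if it
  decreases the parent's impurity; otherwise the node becomes a majority
  leaf;
* node networks are trained by mini-batch gradient descent on softmax
  cross-entropy (backpropagation implemented from scratch in numpy), with
  the L2 term λ·w applied to weights only, and a deliberately short budget
  (2 epochs by default — more overfits the tiny positive class);
* children re-train fresh networks on only the samples routed to them.

The surrounding pipeline — feature analysis (correlation matrix,
select-K-best with a mean-score threshold, RFE-CV importance scores in
[0, 1]), deterministic imbalance-ratio subsampling, macro-averaged
evaluation, and a synthetic generator — makes the whole method exercisable
without the (undistributed) genome datasets.

### Imbalance-ratio construction

`target_counts(n_pos, n_neg, ratio)` keeps all negatives and retains
`round_half_up(n_neg / ratio)` positives; when that exceeds the supply it
keeps all positives and subsamples `n_pos × ratio` negatives instead. This
rule reproduces, exactly, all 54 (dataset × ratio) count pairs of the
published benchmark ladders for the animal / plant / human / arabidopsis /
virus datasets.

### Metrics

Sensitivity (SE) is positive-class recall, specificity (SP) negative-class
recall; F1 and precision are **macro** averages with a 0/0 → 0 convention.
An all-negative classifier therefore prints SE 0.00, SP 1.00,
F1 = Prec = 0.50 — visible failure instead of inflated accuracy.

## Worked example

```sh
hdnn simulate --n-positive 60 --n-negative 600 --n-features 8 \
     --effect-size 6 --n-informative 4 --seed 1 --out demo.csv
# wrote 660 samples (60+/600-) to demo.csv
hdnn subsample --in demo.csv --ratio 100 --seed 3 --out demo_ir100.csv
# IR 1:100: kept 6+/600- -> demo_ir100.csv      (round(600/100) = 6 positives)
hdnn train --in demo.csv --config cfg.yaml --model model.json --seed 5
# grew tree: depth 1, 1 internal node(s) -> model.json
hdnn evaluate --model model.json --in demo.csv
```

prints

```json
{"acc": 0.99, "se": 0.93, "sp": 1.0, "f1": 0.98, "prec": 0.99}
```

i.e. on this easy 6-SD-separated table the tree recovers 93% of the
positives while keeping every negative. `hdnn sweep --ladder virus ...`
repeats subsample → split → train → evaluate across a whole IR ladder and
writes one report row per ratio; ratios left with too few samples to split
are marked `skipped`. The library mirrors every subcommand
(`hdnn.grow_tree`, `hdnn.ir_sweep`, ...).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline subsampling counts (positives or negatives retained
at selected imbalance ratios for the named benchmark datasets) by applying
the package's count rule to the dataset manifests — verified end to end by
actually subsampling a synthetic table of the same shape — and writes them
as JSON.

See `docs/methods.md` for the model's assumptions, defaults and known
limitations.
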