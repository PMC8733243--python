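# Methods

## Model

### Node networks

Each internal tree node holds a dense feed-forward network. The forward
pass per layer is the propagated input `I_m = Σ_k O_k·w_km + w_0m`
followed by ReLU on hidden layers and the identity on the 2-unit output;
the per-unit threshold that sometimes appears in neuron models is absorbed
into the bias (set to 0). The class decision is `argmax` of the two output
scores, with ties broken to the negative class. Softmax before the argmax
would not change any routing decision, so raw scores are used.

The loss is softmax cross-entropy: it is the unique standard choice for
which the output-layer error signal is exactly `a(z) − y`, the form the
backward pass accumulates. Gradients on weight entries are
`(1/m)·Σ + λ·w` and on bias entries `(1/m)·Σ` — the regularizer
deliberately skips biases and is **not** scaled by `1/m`; the
finite-difference oracle in the tests differentiates the matching
objective `mean CE + (λ/2)·Σw²`. The optimizer is plain mini-batch
gradient descent; no momentum or adaptive scheme is used.

Dropout is inverted (train-time scaling by `1/(1−rate)`), so inference
needs no rescaling and is a pure function of the input. Default rate 0.2,
applied after the 256- and 16-unit layers of the default
`[d, 512, 256, 64, 32, 16, 2]` topology.

Defaults that matter:

| parameter | default | why |
|---|---|---|
| epochs | 2 | longer schedules overfit the few positives at high IR |
| batch size | 32 | standard; full batches would starve the minority signal |
| learning rate | 0.01 | stable for 1/sqrt(fan-in) Gaussian init across the tested widths |
| λ | 0.0 | regularization available but off unless configured |
| init | N(0, 1/fan-in), zero biases | keeps pre-activation variance ~constant per layer |

### Tree growth

At each node: train a fresh network on the samples reaching the node,
route every sample by its argmax decision, and score the induced split by
weighted Gini impurity `(n_L/n)·G(L) + (n_R/n)·G(R)`, `G = 1 − Σ p_j²`.
The split is accepted only if it reduces impurity by at least
`min_impurity_decrease` (default 1e−4) and depth < `max_depth` (default
5), node size ≥ `min_samples_split` (default 20), and both sides are
non-empty. Otherwise the node is a leaf labeled with its majority class,
ties to negative (the overall majority). Child nodes re-learn from the
**original features** of their subset — not from parent hidden
activations — with per-node seeds derived deterministically from the grow
seed. A pure or single-class node is a valid depth-0 model, not an error.

The literal split-acceptance pseudocode this design descends from
initializes its threshold at 0 and fires on `g < 0`, which a Gini value
can never satisfy; the working interpretation — track the minimum weighted
Gini and accept impurity-decreasing splits — follows the accompanying
description of Gini as the split cost function. The stopping criteria and
the leaf-labeling rule are this package's conventions; the original
procedure specifies none.

### Imbalance-ratio subsampling

`target_counts` keeps all negatives and retains
`round_half_up(n_neg/ratio)` positives; if that exceeds the positives
available, it keeps all positives and subsamples `n_pos × ratio` negatives
(capped at the supply). Round-half-up is the only rounding consistent with
every published ladder cell (218,154/3,000 = 72.72 → 73 and
218,154/4,000 = 54.54 → 55; floor fails both). Which rows are kept is a
uniform draw without replacement, seeded; each ladder ratio is sampled
independently (nested subsets are not attempted — whether the original
benchmarks nested theirs is unknown). Rows keep their original order.

### Feature analysis

* Correlation: Pearson product-moment; constant features get a zero
  row/column (flagged with a warning) instead of NaN.
* Select-K-best: the per-feature score is the one-way ANOVA F statistic
  between the classes (the filter itself is unspecified upstream; F is the
  standard univariate choice for numeric features with binary labels).
  Selection keeps scores ≥ the mean score — `≥`, so an all-equal vector
  selects everything rather than nothing.
* RFE-CV: recursive elimination of one feature per iteration with an
  L2-regularized logistic regression on standardized features,
  cross-validated with stratified k-folds (default 5, seeded). Scores are
  elimination ranks rescaled to [0, 1] with 1 = most important. The base
  learner is this package's choice; the report records it.
* The combined mask is the AND of both selectors. On the real hairpin
  benchmarks both selectors reportedly keep all 29 features, making the
  combination an identity there; on synthetic data only the ordering
  property (informative features outrank noise) is asserted.

### Metrics

Macro averaging was chosen because it is the only convention that
reproduces the degenerate published rows in which an all-negative
classifier at extreme IR prints F1 = Prec = 0.50 alongside SE = 0.00:
per-class precision/recall/F1 with 0/0 → 0, averaged unweighted over the
two classes. SE is positive-class recall and SP negative-class recall;
one published table block prints SP/SE values that contradict these
definitions (apparently swapped columns), and the definitions here are
fixed as stated rather than following any inconsistent cell. Display
rounding is 2 decimals; JSON reports keep full precision.

## Synthetic data

Negatives are drawn from a zero-mean equicorrelated Gaussian
(`x = sqrt(ρ)·z0 + sqrt(1−ρ)·ε`, unit marginal variance); positives are
identical with the first `n_informative` features shifted by
`effect_size` SDs; rows are shuffled by a seeded permutation. Defaults: 29
features, ρ = 0, effect sizes per test as stated in each scenario (6 SD
for separability checks, 2–3 SD for selector-ordering checks, 0 for null
checks). The generator emulates the *shape* of hairpin feature tables —
dimensionality, imbalance, tunable separation — and none of their
distributional quirks (skew, heavy tails, feature-specific scales,
label noise). A green separability test therefore establishes that the
pipeline recovers a known signal, not that published genome-scale results
are reproduced; those datasets are not distributed and are out of scope.

The five dataset manifests carry the published class counts. The plant
positive count is recorded as 2,172 (consistent with the 1:1 ladder row
and the 117,101 total); the prose figure of 2,154 circulating for the same
dataset is inconsistent with both by 18.

## Numerical choices

* Gradient checks use central differences with step 1e−6 and relative
  tolerance 1e−5, with random non-zero biases so no pre-activation sits on
  the ReLU kink (zero-bias inits land there exactly whenever an upstream
  layer is fully clipped, making finite differences invalid).
* CSV round-trips are bit-exact: floats are written as `%.17g` and parsed
  with round-trip precision.
* Argmax ties route/classify to index 0 (negative class), matching the
  leaf-label tie rule.
* Stratified splitting (default 70/30, seeded) is mandatory: at IR 1:5000
  an unstratified split can leave a test set with zero positives.
* All seeds are fanned out deterministically (hash of seed + stage name in
  the CLI; affine maps per node/ratio in the library), keeping every
  documented entry point reproducible end to end.

## Known limitations

* Node networks are trained once per node; there is no global fine-tuning
  pass over the assembled tree.
* Routing is hard (argmax); no soft/probabilistic routing, pruning,
  ensembling, or multiclass support.
* The 29 hairpin descriptors themselves are taken as given; computing them
  from RNA sequences is explicitly out of scope.
* With very few positives at a node, the short training budget can leave
  the node network at the all-negative solution; the sweep reports such
  ratios honestly (SE 0, macro F1 ≈ 0.5) rather than resampling.
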