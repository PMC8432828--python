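# Methods

This note documents the model, the procedural choices that were genuinely
open, and the limits of what the bundled benchmarks demonstrate.

## Model and objective

The classifier is a small fully connected network: input dimension *d*
(species), ReLU hidden layers (defaults: 16-8-4 for the Iris benchmark,
32-8-4 for 50-species count tables), and a 2-logit head passed through a
softmax. The identity is used before the softmax: a ReLU there would forbid
negative logits and destroy the signed score the hinge needs.

Two objectives share this architecture:

* **softmax** — mean cross-entropy plus `α·Σ_l ||W_l||²` (weights only,
  biases unregularized), the conventional baseline;
* **optsep** — `(1/2)||W_L||² + Σ_i max{0, 1 − t_i s_i} + α·Σ_l ||W_l||²`,
  with `t_i = 2y_i − 1` and `s_i = logit₁ − logit₀`. The hinge sum (not
  mean) over samples mirrors the soft-margin SVM objective, to which the
  loss reduces exactly at zero hidden depth and `α = 0` (a regression test
  asserts this). The `(1/2)||W_L||²` term implements the "margins stay
  finite" constraint: without it the latent classes could be pushed apart
  indefinitely at no cost.

Two readings of the hinge's label slot are possible (the network's own
output, or the true label); the self-referential reading is degenerate — it
can be minimized without fitting the data — so the true label is used, as in
the SVM hinge the loss generalizes.

`α` defaults to 0.01. `C = 2` only: multiclass hinge formulations are out of
scope.

## Training

Training is full batch (every dataset here has at most a few hundred
samples; no batch-size hyperparameter), up to 1000 epochs, with early
stopping: in `abs` mode training stops once the loss has moved by at most
`es_thresh` (default 1e-3) over the last `es_window` (default 5) epochs; in
`rel` mode once the mean over the last window is within 1% of the mean over
the window before. Divergence (non-finite loss) raises with the epoch
number.

Initialization is Glorot-uniform weights with hidden biases at 0.1: with
all-nonnegative inputs (counts, log counts) and zero biases, ReLU units
start dead at high rates. Given a seed, init and training are bit
reproducible.

Two optimizers are implemented:

* **adam** (estimator default) — the standard adaptive choice;
* **gd** — momentum (0.9) full-batch gradient descent with global
  gradient-norm clipping (2.0). The benchmark protocols use `gd`
  deliberately: the extraction step ranks *weight magnitudes*, and weight
  magnitudes under gradient descent grow in proportion to accumulated
  gradient signal, so more discriminative inputs end with larger first-layer
  weights. Adam's per-coordinate normalization makes weakly- and
  strongly-driven weights grow at the same rate, which measurably degrades
  the traced rankings while leaving accuracy unchanged.

A trained net can die: if an entire hidden layer outputs zero for every
sample, the classifier is constant and no gradient can revive it. The
experiment harness detects this structurally (all-zero hidden layer or
constant decision score — no labels involved) and re-draws such runs with
the next deterministically derived seed, the same policy applied to splits
that happen to contain a single class. Every discarded seed is recorded on
the run.

## Extraction

Per experiment, on the **training** samples only (every fitted quantity is
blind to the held-out set; which set the margin tables of the original
study used is not stated anywhere, so this is a package choice):

1. activations of the first hidden layer are computed (it is the layer the
   margin objective separates that is still an affine-then-ReLU function of
   named inputs; deeper layers can be selected for study, but their traced
   "inputs" are latent units, not species);
2. the closest opposite-class pair `z⁺, z⁻` under Euclidean distance spans
   the margin; rows are canonically ordered (lexicographically by
   coordinates) before the pair search so the result cannot depend on
   sample order, and ties resolve to the smallest index pair;
3. `m = z⁺ − z⁻` (the sign convention is fixed; ranking by `|m|` makes the
   choice immaterial), neurons ranked by `|m_j|`, ties to the lower index,
   `top_n` kept;
4. per kept neuron, first-layer input weights ranked by `|w|`
   (`rank_mode="absolute"`) or raw value (`"signed"`, when the direction of
   association matters), ties to the lower feature index, `top_w` kept.

A zero margin (coincident opposing points) produces a warning and falls
back to the tie ordering rather than failing.

Defaults: `top_n = top_w = 2` for the 4-feature Iris benchmark;
`top_n = top_w = 3` (9 slots) for 50-species tables, so that a realistic
indicator set can be represented within a single run while ensemble
frequency still suppresses chance selections.

## Ensembles and frequency ranking

`run_experiments` derives per-run seeds from `(master_seed, run_index,
attempt)` via `SeedSequence`, so batches are reproducible, independent of
execution order, and prefix-stable (the first *n* runs of a larger batch
are identical to a batch of *n*). Two frequency denominators are reported
because both appear in practice: `per_experiment` (share of runs whose
distinct selection contains the species; values may sum past 100) and
`per_slot` (share of all selection slots; sums to 100 up to rounding).
Sorted outputs break frequency ties lexicographically and print one decimal
place; full precision stays in memory.

`evaluate_feature_subset` scores any fit/predict classifier (Random
Forests, SVMs, the softmax net — consumed as black boxes, never
reimplemented) on a chosen species subset over repeated stratified splits,
for downstream comparisons of indicator sets.

## Preprocessing

Count tables are reduced to the top-k species by total abundance over *all*
samples (k = 50 default) and transformed by `log10(x + 1)`. Computing the
filter before the train/test split mirrors the procedure this package
operationalizes and leaks marginal abundance across the split — a
documented caveat, acceptable because the filter uses no labels. No
autoscaling is offered for count tables: equalizing per-species mean and
variance would erase the contrast between rare-but-abundant and ubiquitous
taxa that both the filter and the extractor rely on. Stratified splits
round per-class test counts half-up with a floor of one and a cap of
`n_c − 1`.

## The Iris protocol

The binary Iris subset (setosa vs versicolor, 100 samples) is the
proof-of-concept: separable, with known ground truth (petal length and
width determine the species). Protocol: per-split centered range scaling of
the four cm-scale measurements (subtract the training mean, divide by the
training range), 80:20 stratified splits, hidden layers 16-8-4, `gd`
optimizer at step 0.05, `abs` early stop at 1e-3, up to 1000 epochs,
aggregated over 200 experiments.

Scaling is part of this protocol (not of the count-table path) for two
reasons. Centering: with all-positive raw inputs, hidden units that
specialize on one class grow first-layer weights along that class's raw
*mean* — dominated by whichever features have large values, e.g. sepal
length at ~5 cm — rather than along the class *difference*; after centering
the class means are ±half the difference, so weight growth tracks
discriminative signal only. Range scaling (not variance autoscaling, which
would equalize spreads) simply removes the arbitrary units.

Known limitation: weight tracing on margin-converged models does not drive
the sepal features to exactly zero. Sepal width genuinely separates
borderline setosa/versicolor samples — a converged linear SVM on these data
assigns it a weight comparable to petal width — so a few percent of
selection slots (~5%) go to sepal width no matter how the training is
configured; the petal pair dominates with ~95% of slots and sepal length is
never selected. Runs that report these features at exactly zero are, in our
experience, only obtainable from under-converged models.

## Synthetic communities

The generator emulates the statistical shape of a disturbed-vs-natural
16S survey: defaults of 70 samples split 41/29, 50 species, zero-inflated
negative-binomial counts (structural-zero probability 0.8, NB mean 5,
dispersion 0.5), a rare high-abundance tail (10% of background species at
50× mean), and 5 planted indicators, split between the two habitats. An
indicator's enrichment moves both abundance (NB mean × `10^effect`,
default one decade) and prevalence (structural-zero probability ÷
`10^(effect/2)`): indicator taxa in real surveys are more abundant *and*
more prevalent where they indicate, and under 80% structural zeros a
mean-only shift is nearly invisible at N = 70. At `effect = 0` indicator
columns are distributed exactly as background.

What the generator does **not** emulate: phylogenetic correlation between
species, compositional (closed-sum) coupling, sequencing-depth variation
between samples, and label noise. Passing the recovery benchmark therefore
shows the pipeline can find planted, independent signals in realistically
sparse and overdispersed tables — not that it resolves correlated or
compositional structure in real surveys. With very large *d* and a heavy
high-abundance tail, the top-k abundance filter itself can drop genuine
indicators before the model ever sees them; that is a property of the
filtering procedure, preserved deliberately.

The recovery benchmark runs 20 independent community draws × 50 experiments
(defaults throughout) and asks that all 5 planted indicators rank in the
top 10 by selection frequency; the problem sizes (200 Iris experiments, 20
× 50 community experiments) keep the full evaluation at a few CPU-minutes
while leaving the ensemble large enough for stable frequencies.

## Numerical and degenerate-input conventions

All tie-breaks are deterministic and documented above (stable argsort
everywhere). Prediction ties (equal softmax probabilities) resolve to the
lower class index. Softmax probabilities are clipped at 1e-12 inside the
cross-entropy. Empty classes, mismatched dimensions, negative counts,
non-binary labels, and out-of-range `top_n`/`top_w`/`k` raise immediately
with specific messages rather than propagating bad values.
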