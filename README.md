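# optsep

Margin-maximizing deep networks for identifying **indicator species** in
microbial abundance tables.

Ecological surveys (e.g. 16S rRNA amplicon studies) produce a count table
**X** with *N* samples as rows and *d* OTU/ASV species as columns, plus a
binary habitat label per sample (0 = natural, 1 = disturbed). Beyond
predicting the habitat of new samples, the scientifically valuable output is
the short list of taxa whose abundances *drive* the distinction — the
indicator species that let ecologists monitor a site with a handful of
assays instead of a full community profile. `optsep` implements a deep
feature extractor for exactly this task: it is agnostic to the nonlinear
structure of the community data (a ReLU network learns whatever interactions
exist) yet yields latent features that trace back to named species.

## Method

Three components, run as an ensemble over many random initializations:

1. **A margin-maximizing classifier.** A small feedforward net
   (ReLU hidden layers, 2-logit softmax head) is trained under a hinge
   objective inspired by the soft-margin SVM:

   ```
   min   (1/2)·||W_L||²  +  Σᵢ max{0, 1 − tᵢ·sᵢ}  +  α·Σₗ ||W_l||²
   ```

   with true label `tᵢ = 2yᵢ − 1 ∈ {−1,+1}` and signed score
   `sᵢ = logit₁(i) − logit₀(i)`. The hinge pushes the two habitat classes
   apart in every latent layer, while the final-layer weight norm keeps the
   separating margins finite; with zero hidden depth and `α = 0` the
   objective reduces exactly to the linear SVM. A conventional softmax
   (cross-entropy) loss is available as the baseline.

2. **Separation-direction weight tracing.** In the first hidden layer,
   find the closest pair of opposite-class samples `z⁺, z⁻` (the pair that
   spans the separating margin), form the direction of separation
   `m = z⁺ − z⁻`, keep the `top_n` neurons with the largest `|mⱼ|`, and for
   each keep the `top_w` largest-magnitude first-layer input weights. The
   input species attached to those weights are the candidate indicators of
   that run.

3. **Ensemble frequency ranking.** Training is repeated over many seeded
   experiments (fresh stratified split, fresh initialization); species are
   ranked by the percentage of experiments (or of selection slots) in which
   they were traced. High-frequency species are the indicator set.

Preprocessing follows standard sparse-count practice: keep the top-k species
by total abundance (default 50), transform counts by `log10(x + 1)`, and do
**not** autoscale — per-species scale differences are informative here.

## Worked example

Proof of concept on the bundled Fisher Iris table, restricted to its first
two species (setosa vs versicolor, 100 samples, 4 measurements):

```
$ optsep iris-demo --experiments 200 --seed 1 --out-dir iris_out
{
  "softmax": {
    "train_accuracy_avg": 1.0,
    "test_accuracy_avg": 1.0,
    "margins_avg": [0.886, 1.378, 2.183]
  },
  "optsep": {
    "train_accuracy_avg": 1.0,
    "test_accuracy_avg": 1.0,
    "margins_avg": [1.375, 2.966, 6.225]
  }
}
$ head -4 iris_out/optsep/feature_frequency.tsv
feature_id      frequency_percent
petal_length    49.1
petal_width     46.1
sepal_width     4.8
```

(margins truncated to three decimals here). Both objectives classify the
separable problem perfectly, but the margin-maximizing loss widens the
inter-class separating margin in every hidden layer (~1.5–3× the softmax
baseline, growing with depth). The traced features are dominated by the two
petal measurements (~95% of all selection slots) — the features domain
knowledge says determine the species — with sepal length never selected;
sepal width, which genuinely separates borderline samples of these two
species, retains a small share.

The same pipeline on a synthetic two-habitat community with planted
indicators:

```
$ optsep simulate --seed 1 --out-dir sim
$ optsep preprocess --counts sim/counts.tsv --labels sim/labels.tsv --out-dir prep
$ optsep benchmark --counts prep/counts_preprocessed.tsv --labels sim/labels.tsv \
      --experiments 5 --master-seed 1 --out-dir bench
avg test accuracy: 0.929
$ head -5 bench/feature_frequency.tsv
feature_id      frequency_percent
sp0037  100.0
sp0025  80.0
sp0022  60.0
sp0047  60.0
```

`sim/planted_indicators.tsv` lists the ground-truth planted species, so the
ranking can be checked against truth. Every command writes a
`manifest.json` with the resolved parameters and seeds for exact re-runs.

The library surface mirrors scikit-learn: `MarginMaxNetClassifier` is a
standard estimator (`fit`/`predict`/`predict_proba`/`get_params`), the
preprocessing steps are transformers, and everything composes with sklearn
model selection.

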