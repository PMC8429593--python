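# Methods

## The cleansing procedure

`udclean` triages a labeled classification dataset by ensemble
cross-validation voting. Given `n` model specifications and `k` folds
(stratified by class by default), each spec is fitted on the `k−1` training
folds of every fold, giving `n·k` models per round. Every model then casts a
boolean vote per item: *true* iff it predicts the item's assigned label. The
per-item success count `s_j` is the column sum of this vote matrix.

Items are triaged by fractional thresholds of the vote total `T` (`T = n·k`
under all-items voting, `T = n` under out-of-fold voting):

- `s_j ≥ τ_high·T` → correct
- `s_j ≤ τ_low·T` → incorrect
- otherwise → noisy

Defaults are `τ_low = 0.3`, `τ_high = 0.7`. The published account of the
three populations is qualitative ("high, low, and medium values of s"), so
the cutoffs are a design choice here: they bracket the fair-coin region
`p ≈ 0.5` symmetrically and are deliberately far from both boundaries so
that a single eccentric model cannot move an item between categories.
Boundary items are assigned deterministically (`≥` → correct, `≤` →
incorrect); there is no randomized tie-break. Both thresholds are
config-overridable.

**Voting scope.** The default `all_items` scope applies every trained model
back onto the full training set, the literal reading of the procedure
("applied back on the same training data"). Because each model has seen
`(k−1)/k` of the items during fitting, this scope only works with backends
regularized enough not to memorize mislabeled items; the reference backends
are chosen accordingly, and a `memorize` backend (1-NN) is registered to
test the failure boundary. The stricter `out_of_fold` scope, where a model
votes only on its held-out fold (giving exactly `n` votes per item), is
available as an anti-memorization mode.

**Rounds.** Multi-round operation re-runs the full procedure on the
survivors of the previous round, with folds reassigned (seed + round index)
and all models retrained from scratch — warm starts would let round-1 errors
propagate. A round that removes nothing is a fixed point and terminates the
run early. One fold assignment is shared by all architectures within a
round, so the architectures vote on identical train/validation partitions
and their votes differ only by inductive bias, not by data exposure.

**Removal policy.** The default `incorrect_and_noisy` removes both flagged
categories, the policy used in the label-flip benchmarks. `noisy_only`
matches the X-ray-style use case where no labels are suspected wrong but
uninformative images should be excluded; `incorrect_only` is the complement.
If a policy empties an entire class the surviving dataset is flagged
untrainable (`meta['untrainable']`) with a warning rather than an error, so
callers can inspect the audit trail.

## Screening

Before cleansing, each candidate spec is fitted across the `k` folds and its
pooled out-of-fold predictions (one per item, `N` in total) are tested
against chance accuracy `1/C` with an exact one-sided binomial test. A
candidate is eligible iff `p < α` (default 0.05); the dataset is trainable
iff some candidate is eligible. Pooling across folds gives one test per
candidate at maximal `n`; per-fold testing would multiply comparisons with
no benefit. The mean of each backend's per-epoch validation accuracies is
reported but not gated — the significance criterion is the only published
hard rule, and iterative and non-iterative backends would otherwise need
different epoch-accuracy thresholds. `α` itself is a documented choice: the
source material says only "statistically significant".

## Reference backends

The procedure is backend-agnostic; the published experiments used GPU-scale
ResNet/DenseNet CNNs, which are out of scope at desk scale. The reference
backends are surrogates that preserve the property UDC actually relies on —
a regularized learner fits the majority-consistent signal and cannot fit
isolated mislabeled items:

- `linear`: scikit-learn logistic regression, inverse-regularization `C`
  (default 1.0), `class_weight="balanced"`.
- `mlp`: scikit-learn MLP, one hidden layer (16 or 32 units in the default
  ensemble), L2 `alpha` (1e-2/1e-1), early stopping on a 15% validation
  split with patience 10 (the published training stack lists early stopping
  without a patience value; 10 is the default here), max 200 epochs.
  `MLPClassifier` has no class-weight support, so balancing is applied by
  deterministic seeded oversampling of minority classes.
- `small_cnn` (image mode): a fixed bank of 8 seeded random 3×3 filters,
  ReLU, 2×2 mean pooling, logistic head. Untrained convolutional features
  are a standard cheap stand-in for a learned stem and keep the backend
  fully deterministic. Optional horizontal-flip augmentation is image-mode
  only and off by default.

Default ensembles: `n=3` (logreg, mlp16, mlp32) for binary experiments,
`n=4` (+ logreg at `C=0.1`) for the 4-class experiments, matching the
published architecture counts. All fits are deterministic given
(spec, seed, data); per-model seeds combine the run seed, spec seed and fold
index. Hyperparameters are config-overridable throughout, since the
published per-architecture settings are not fully tabulated.

Image preprocessing resizes to 224×224 RGB and normalizes with the ImageNet
channel means (0.485, 0.456, 0.406) and standard deviations (0.229, 0.224,
0.225); grayscale input is replicated to three channels.

## Synthetic benchmark generator

`make_dataset` draws `C` isotropic Gaussian classes at centroids placed on a
scaled standard-basis simplex so every pair is exactly
`separation · noise_sigma` apart (requires `dim ≥ C`). At the default
separation of 6σ a linear classifier on clean data exceeds 99% holdout
balanced accuracy, mirroring the ≈99% clean baselines of the published
binary benchmark. Image mode renders 32×32 per-class blob templates plus
pixel noise (not 224×224, to keep desk-scale runtimes; `preprocess_images`
upscales when needed).

`inject_label_noise` flips exactly `round_half_up(𝓃_c · N_c)` labels per
class — exact counts make recovery metrics deterministic — selected by
seeded shuffle. Binary flips land on the other class; multi-class targets
are uniform over the other `C−1` classes by default (matching the "evenly
distributed" published design) or follow an explicit zero-diagonal
row-stochastic confusion matrix. The flip record (id, original, assigned) is
returned and never leaks into the dataset. `split_blind_test` produces the
stratified clean blind test set before any corruption.

What the generator does *not* emulate: intra-class visual diversity,
genuinely ambiguous items (its "noisy" triage bin on separable data is
nearly empty), class imbalance unless configured, and feature distributions
where label errors correlate with the features. Passing benchmarks here
therefore demonstrate the mechanics and accounting of the procedure, not its
performance on photographic or clinical data.

## Evaluation statistics

- **Balanced accuracy**: unweighted mean of per-class recalls
  (scikit-learn's implementation behind the package surface).
- **Recovery**: precision/recall of removed ids against the flip record;
  undefined denominators are reported as absent, never as 0.
- **Cohen's kappa**: marginal-product expected agreement; point estimate and
  large-sample standard errors via `statsmodels.stats.inter_rater`; the
  test against κ=0 is one-sided on the null SE. Degenerate tables with
  `p_e = 1` yield an explained absent κ. Exact small-sample inference is out
  of scope. `reader_study` computes κ on the UDC-correct and UDC-noisy
  subsets, tests each against chance, and compares the two κ's with a
  large-sample z test; a seeded reading-order randomizer is included as the
  fatigue-bias control.
- **Cohen's d**: pooled-SD standardized mean difference of replicate metric
  values, `p` from Welch's two-sample test (the published table's test is
  unstated; Welch is the conservative default). Zero pooled SD with equal
  means gives `d = 0`; with unequal means an infinite-effect flag.
- **Contamination check**: per replicate, a stratified validation slice is
  held out of the training set; one backend is fitted on the remainder and
  again on remainder + test set, and the balanced validation accuracies are
  compared. A negative mean difference flags test-label quality problems.

## Numerical and scale choices

Benchmark problem sizes were chosen so the full suite and the acceptance
script each run in well under a minute on one CPU: binary scenarios use
1,000 items/class in 8 dimensions (≈2,000 training items after the 1/3
blind split, the published ≈2:1 train:test ratio at 1/12 scale), 4-class
scenarios 500 items/class, five replicate seeds per reported number.
Property tests use 40–400 items/class.

Known desk-scale deviations from the published behaviour, both verified
empirically and reflected in the tests:

- Regularized linear/MLP surrogates are far more label-noise-robust than
  large CNNs, so the *pre*-cleansing accuracy degrades only mildly at
  moderate binary noise (the published 63.1% at 30%/30% appears here as
  ≈99% "before"); the gain from cleansing shows at high rates (≥60%) and in
  the recovery/after-cleansing numbers, which are the quantities the
  benchmark bounds target.
- Under 50%/50% symmetric binary corruption the surrogates do not collapse
  to predicting a single class (the published one-class-rejection mode);
  votes mix and most items land in `noisy`. The failure is still detected —
  screening declares the dataset untrainable on every tested seed — and the
  corresponding test asserts that joint form.
- The contamination check's degradation signal needs overlapping classes
  (separation ≈2.5σ) to be visible, because at 6σ a plurality learner is
  indifferent to injected random labels.

## Limitations

Thresholds are fixed fractions, not learned from the `s_j` histogram
(histogram export is provided; modality detection is not). Image-mode
voting requires the caller to preprocess images into feature matrices.
Multi-rater agreement (Fleiss) and GPU training are out of scope.
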