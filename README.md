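# udclean — Untrainable Data Cleansing

Label noise is the silent killer of supervised classifiers, and in medical
imaging it is endemic: outcome labels can be wrong (a viable embryo labeled
non-viable because the patient, not the embryo, prevented pregnancy) or the
data itself can be uninformative (an unreadable chest X-ray that supports no
diagnosis). Manual review is often impossible — labels may have no accessible
ground truth, and privacy rules can forbid looking at the images at all.

`udclean` implements **Untrainable Data Cleansing (UDC)**, an automated
triage of a labeled dataset into *correct*, *incorrect* (mislabeled) and
*noisy* (uninformative) items, using nothing but the training process itself.
It is aimed at practitioners building image or feature-vector classifiers who
suspect their training (or test!) labels, and at anyone who needs a
benchmarked synthetic label-noise testbed.

## The method

Train `n` model architectures across `k` stratified cross-validation folds
and apply each of the `n·k` fitted models back to every item. For item *j*,
count the successful predictions

&nbsp;&nbsp;&nbsp;&nbsp;*s<sub>j</sub>* = #{ models that predict item *j*'s assigned label },&nbsp;&nbsp; 0 ≤ *s<sub>j</sub>* ≤ *n·k*.

Viewing each item as a weighted coin with probability *p* of being predicted
correctly, correctly-labeled items have *p* ≫ 0.5, mislabeled items *p* ≪ 0.5
(models trained on the majority-consistent signal contradict them), and
uninformative items *p* ≈ 0.5. The *s<sub>j</sub>* histogram is therefore
thresholded at fractions (τ<sub>low</sub>, τ<sub>high</sub>) = (0.3, 0.7) of
*n·k*:

- *s<sub>j</sub>* ≥ τ<sub>high</sub>·*n·k* → **correct**
- *s<sub>j</sub>* ≤ τ<sub>low</sub>·*n·k* → **incorrect**
- otherwise → **noisy**

Removing incorrect and/or noisy items cleanses the dataset; the procedure can
be applied for several rounds. A pre-flight **screening** gate (exact
one-sided binomial test of pooled out-of-fold accuracy against chance 1/C)
rejects datasets with no learnable signal — e.g. 50%/50% symmetric binary
corruption, where no majority of good labels remains and cleansing is
impossible.

The package also ships the supporting apparatus: a synthetic generator of
separable datasets with exact, recorded per-class label flips; balanced
accuracy / sensitivity / specificity / flip-recovery metrics; Cohen's kappa
reader-consensus tests with hypothesis reporting; Cohen's *d* effect sizes;
and a test-set contamination check (inject a suspect test set into training
and watch validation accuracy).

## Worked example

`examples/cleanse_noisy_dataset.py` generates a separable binary dataset
(603 training items after a blind split), flips 30% of each class's training
labels, runs one UDC round (3 backends × 5 folds) and retrains on the
survivors:

```
training items: 603, injected flips: 181
triage: {'correct': 420, 'incorrect': 176, 'noisy': 7}
removed 183 items (flip recall 98.9%, precision 97.8%)
blind balanced accuracy: 99.7% before -> 100.0% after cleansing
```

The 181 injected mislabels collect almost exactly in the `incorrect` bin
(low *s<sub>j</sub>*): 98.9% of them are removed, and only 4 of the 183
removed items were not injected flips. The other examples cover the
noise-rate grid (`noise_grid.py`, including the ≥80% *uncleansable* regime),
screening (`screen_before_cleansing.py`), reader agreement
(`reader_agreement.py`) and test-set auditing (`test_set_contamination.py`).

A thin CLI mirrors the library: `udclean generate | screen | cleanse |
evaluate | experiment` (exit code 3 marks an untrainable dataset, 2 a
validation error).

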