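"""Pre-UDC eligibility screening.

Before cleansing, each candidate model configuration is checked for learnable
signal: it is fitted across k folds, its pooled out-of-fold validation
predictions are compared with the assigned labels, and an exact one-sided
binomial test asks whether the accuracy exceeds chance (1/C). Candidates that
cannot beat chance at significance alpha are screened out; a dataset where no
candidate survives is declared untrainable — the failure mode of datasets
whose labels carry no learnable relation to the features (e.g. near-symmetric
50%/50% label corruption in both classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from . import backends
from .backends import ModelSpec
from .udc_core import LabeledDataset, assign_folds


@dataclass
class CandidateScreen:
    """Screening record for one candidate model configuration."""

    spec: ModelSpec
    mean_epoch_accuracy: float
    n_predictions: int
    n_correct: int
    chance: float
    p_value: float
    eligible: bool


@dataclass
class ScreeningReport:
    """Per-candidate screening outcomes and the overall trainability verdict."""

    candidates: list
    alpha: float
    dataset_trainable: bool
    reason: str | None = None

    def eligible_specs(self) -> list:
        return [c.spec for c in self.candidates if c.eligible]


def screen_hyperparameters(
    dataset: LabeledDataset,
    candidates: list,
    k: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> ScreeningReport:
    """Screen candidate model configurations for above-chance validation accuracy.

    Each candidate is fitted on the k-1 training folds of every fold and its
    held-out predictions are pooled (n_predictions = N, a single test per
    candidate). Eligibility: exact one-sided binomial p-value of n_correct
    successes against chance 1/C below alpha. Degenerate datasets yield
    ``dataset_trainable=False`` with a reason rather than an exception.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    chance = 1.0 / dataset.n_classes
    present = np.unique(dataset.labels)
    if len(present) < 2:
        return ScreeningReport(
            candidates=[],
            alpha=alpha,
            dataset_trainable=False,
            reason="degenerate dataset: fewer than two classes present",
        )
    counts = dataset.class_counts()
    if counts[present].min() < k:
        small = int(present[np.argmin(counts[present])])
        return ScreeningReport(
            candidates=[],
            alpha=alpha,
            dataset_trainable=False,
            reason=(
                f"degenerate dataset: class {dataset.class_names[small]!r} has "
                f"fewer than k={k} items"
            ),
        )
    folds = assign_folds(dataset, k, seed=seed, stratified=True)
    records = []
    for spec in candidates:
        n_correct = 0
        summaries: list[float] = []
        for f in range(k):
            train_mask = folds.fold_of_item != f
            model = backends.fit(
                spec,
                dataset.features[train_mask],
                dataset.labels[train_mask],
                fold_index=f,
                fit_seed=(seed * 1_000_003 + spec.seed * 101 + f) % (2**31),
            )
            held = ~train_mask
            pred = backends.predict(model, dataset.features[held])
            n_correct += int(np.sum(pred == dataset.labels[held]))
            summaries.extend(model.fit_summary)
        n_pred = dataset.n_items
        p = binomtest(n_correct, n_pred, chance, alternative="greater").pvalue
        records.append(
            CandidateScreen(
                spec=spec,
                mean_epoch_accuracy=float(np.mean(summaries)),
                n_predictions=n_pred,
                n_correct=n_correct,
                chance=chance,
                p_value=float(p),
                eligible=bool(p < alpha),
            )
        )
    return ScreeningReport(
        candidates=records,
        alpha=alpha,
        dataset_trainable=any(r.eligible for r in records),
    )
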