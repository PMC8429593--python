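"""Measurement: classification metrics, flip-recovery accounting, inter-rater
agreement (Cohen's kappa), effect sizes (Cohen's d), and the test-set
contamination check.

Conventions
-----------
Balanced accuracy is the unweighted mean of per-class recalls. Flip recovery
treats the injected-flip record as ground truth: recall is the fraction of
injected mislabels that cleansing removed, precision the fraction of removed
items that were injected mislabels. Kappa uses the marginal-product expected
agreement with large-sample standard errors; effect sizes use the pooled-SD
standardized mean difference with a Welch two-sample p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score
from statsmodels.stats import inter_rater

from . import backends
from .udc_core import LabeledDataset, UDCConfig
from .synthetic import FlipRecord


# ---------------------------------------------------------------------------
# classification metrics


def balanced_accuracy(truth, predicted) -> float:
    """Unweighted mean of per-class recalls over the classes present in truth."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"truth has {truth.shape} entries but predicted has {predicted.shape}"
        )
    return float(balanced_accuracy_score(truth, predicted))


def sensitivity_specificity(truth, predicted, positive_class) -> tuple:
    """(sensitivity, specificity) of ``predicted`` for one positive class.

    Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP). A side with no items
    in truth yields ``None`` for the corresponding rate.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    pos = truth == positive_class
    pred_pos = predicted == positive_class
    sens = float(np.mean(pred_pos[pos])) if pos.any() else None
    spec = float(np.mean(~pred_pos[~pos])) if (~pos).any() else None
    return sens, spec


# ---------------------------------------------------------------------------
# flip recovery


@dataclass
class RecoveryMetrics:
    """How well removal recovered the injected label flips.

    precision = |flipped ∩ removed| / |removed|; recall = |flipped ∩ removed|
    / |flipped|. Undefined denominators are reported as ``None``, never 0.
    """

    n_removed: int
    n_flipped: int
    n_recovered: int
    precision: float | None
    recall: float | None


def recovery_metrics(
    removed_ids, flip_record: FlipRecord, dataset: LabeledDataset | None = None
) -> RecoveryMetrics:
    """Score removed ids against the ground-truth flip record."""
    removed = set(np.asarray(removed_ids).tolist())
    flipped = set(np.asarray(flip_record.flipped_item_ids).tolist())
    if dataset is not None:
        known = set(dataset.item_ids.tolist())
        stray = (removed | flipped) - known
        if stray:
            raise ValueError(f"ids not present in the dataset: {sorted(stray)[:5]}")
    hit = len(removed & flipped)
    return RecoveryMetrics(
        n_removed=len(removed),
        n_flipped=len(flipped),
        n_recovered=hit,
        precision=hit / len(removed) if removed else None,
        recall=hit / len(flipped) if flipped else None,
    )


# ---------------------------------------------------------------------------
# Cohen's kappa


@dataclass
class KappaResult:
    """Cohen's kappa with large-sample standard errors.

    ``p_value`` is the one-sided test of kappa > 0 using the null-hypothesis
    standard error ``se_null``; ``se`` is the large-sample SE of the estimate.
    ``kappa`` is ``None`` (with ``reason``) when expected agreement is 1.
    """

    kappa: float | None
    p_o: float
    p_e: float
    se: float | None
    se_null: float | None
    p_value: float | None
    n: int
    reason: str | None = None


def cohens_kappa(rater_a, rater_b) -> KappaResult:
    """Agreement between two label vectors beyond chance.

    kappa = (p_o - p_e) / (1 - p_e), with p_e the marginal-product expected
    agreement over the shared label alphabet.
    """
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two paired ratings")
    alphabet = np.union1d(np.unique(a), np.unique(b))
    table = pd.crosstab(
        pd.Categorical(a, categories=alphabet),
        pd.Categorical(b, categories=alphabet),
        dropna=False,
    ).to_numpy()
    p_o = float(np.trace(table) / n)
    marg_a = table.sum(axis=1) / n
    marg_b = table.sum(axis=0) / n
    p_e = float(np.dot(marg_a, marg_b))
    if p_e >= 1.0 - 1e-12:
        return KappaResult(
            kappa=None, p_o=p_o, p_e=p_e, se=None, se_null=None, p_value=None, n=n,
            reason="expected agreement is 1 (both raters constant and equal); "
            "kappa is undefined",
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = inter_rater.cohens_kappa(table, return_results=True)
    return KappaResult(
        kappa=float(res.kappa),
        p_o=p_o,
        p_e=p_e,
        se=float(res.std_kappa),
        se_null=float(res.std_kappa0),
        p_value=float(res.pvalue_one_sided),
        n=n,
    )


# ---------------------------------------------------------------------------
# reader study


@dataclass
class ReaderStudyReport:
    """Reader-consensus comparison between UDC-correct and UDC-noisy subsets.

    Tests the two hypotheses of the consensus design: (1) agreement on the
    noisy subset is no different from chance; (2) agreement on the clean
    subset is greater than chance. ``p_value_difference`` tests
    kappa_clean > kappa_noisy by a large-sample z comparison.
    """

    kappa_clean: KappaResult
    kappa_noisy: KappaResult
    kappa_difference: float | None
    z_difference: float | None
    p_value_difference: float | None
    warnings: list = field(default_factory=list)


def randomize_reading_order(item_ids, seed: int = 0) -> np.ndarray:
    """Seeded random presentation order (fatigue/order-bias control)."""
    ids = np.asarray(item_ids)
    return np.random.default_rng(seed).permutation(ids)


def reader_study(
    clean_labels, clean_reader, noisy_labels, noisy_reader
) -> ReaderStudyReport:
    """Compare reader agreement on UDC-correct vs UDC-noisy subsets.

    Each subset pairs the dataset's assigned labels with an independent
    reader's labels; kappa is computed per subset and their difference tested.
    """
    warns = []
    for name, v in (("clean", clean_labels), ("noisy", noisy_labels)):
        if len(np.asarray(v)) < 10:
            warns.append(
                f"{name} subset has fewer than 10 items; agreement tests are underpowered"
            )
    k_clean = cohens_kappa(clean_labels, clean_reader)
    k_noisy = cohens_kappa(noisy_labels, noisy_reader)
    diff = z = p = None
    if k_clean.kappa is not None and k_noisy.kappa is not None:
        diff = k_clean.kappa - k_noisy.kappa
        pooled = np.sqrt(k_clean.se**2 + k_noisy.se**2)
        if pooled > 0:
            z = diff / pooled
            p = float(stats.norm.sf(z))
    return ReaderStudyReport(
        kappa_clean=k_clean,
        kappa_noisy=k_noisy,
        kappa_difference=diff,
        z_difference=z,
        p_value_difference=p,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# effect size


@dataclass
class EffectSizeResult:
    """Standardized mean difference (after - before) / pooled SD."""

    d: float
    p_value: float | None
    infinite: bool = False


def cohens_d(before, after) -> EffectSizeResult:
    """Cohen's d of ``after`` relative to ``before`` replicate metric values.

    Pooled SD uses (n-1)-weighted variances; the p-value is a Welch two-sample
    comparison of the replicates. Zero pooled SD with equal means gives d=0;
    with unequal means the effect is flagged infinite.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if len(b) < 2 or len(a) < 2:
        raise ValueError("need at least two replicates per group")
    diff = a.mean() - b.mean()
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        if diff == 0:
            return EffectSizeResult(d=0.0, p_value=None)
        return EffectSizeResult(
            d=float(np.inf) * np.sign(diff), p_value=None, infinite=True
        )
    t = stats.ttest_ind(a, b, equal_var=False)
    return EffectSizeResult(d=float(diff / pooled), p_value=float(t.pvalue))


# ---------------------------------------------------------------------------
# contamination check


@dataclass
class ContaminationReport:
    """Validation accuracy with vs without the test set merged into training.

    A drop under injection flags poor-quality test labels: if the test set
    carried clean labels, adding it could only reinforce the learnable signal.
    """

    acc_train_only: np.ndarray
    acc_with_test: np.ndarray
    mean_difference: float
    se_difference: float
    n_replicates: int

    @property
    def degraded(self) -> bool:
        return self.mean_difference < 0


def contamination_check(
    train: LabeledDataset,
    test: LabeledDataset,
    config: UDCConfig,
    n_replicates: int = 5,
    val_fraction: float = 0.2,
) -> ContaminationReport:
    """Fit on train alone vs train + test; compare validation accuracy.

    Each replicate holds out a stratified validation slice of the training
    set, fits one backend (cycling through the configured specs) on the
    remainder, then refits on remainder + test, and records the balanced
    validation accuracy of both arms. ``mean_difference`` is
    mean(with_test - train_only); a negative value flags test-set quality
    problems.
    """
    from sklearn.model_selection import train_test_split

    if len(set(train.item_ids) & set(test.item_ids)):
        raise ValueError("train and test must have disjoint item ids")
    accs_plain, accs_inject = [], []
    idx = np.arange(train.n_items)
    for r in range(n_replicates):
        spec = config.model_specs[r % len(config.model_specs)]
        seed = (config.seed * 7919 + r) % (2**31)
        fit_idx, val_idx = train_test_split(
            idx, test_size=val_fraction, random_state=seed % 2**32,
            stratify=train.labels,
        )
        X_fit, y_fit = train.features[fit_idx], train.labels[fit_idx]
        X_val, y_val = train.features[val_idx], train.labels[val_idx]
        m = backends.fit(spec, X_fit, y_fit, fit_seed=seed)
        accs_plain.append(balanced_accuracy(y_val, backends.predict(m, X_val)))
        if test.n_items:
            X_aug = np.concatenate([X_fit, test.features])
            y_aug = np.concatenate([y_fit, test.labels])
        else:
            X_aug, y_aug = X_fit, y_fit
        m2 = backends.fit(spec, X_aug, y_aug, fit_seed=seed)
        accs_inject.append(balanced_accuracy(y_val, backends.predict(m2, X_val)))
    plain = np.asarray(accs_plain)
    inject = np.asarray(accs_inject)
    deltas = inject - plain
    se = float(deltas.std(ddof=1) / np.sqrt(len(deltas))) if len(deltas) > 1 else 0.0
    return ContaminationReport(
        acc_train_only=plain,
        acc_with_test=inject,
        mean_difference=float(deltas.mean()),
        se_difference=se,
        n_replicates=n_replicates,
    )
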