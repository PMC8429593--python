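"""The Untrainable Data Cleansing (UDC) algorithm.

Given a labeled dataset, UDC fits n model architectures across k
cross-validation folds and has the resulting n*k models vote on every item:
a vote is "correct" when the model predicts the item's assigned label. The
per-item success count s_j (0 <= s_j <= n*k) separates three populations:

* **correct** labels cluster at high s_j (almost every model agrees with the
  label),
* **incorrect** (mislabeled) items cluster at low s_j (models trained on the
  majority-consistent signal systematically contradict the label),
* **noisy** (ambiguous, uninformative) items sit at intermediate s_j.

Thresholding s_j at fractions (tau_low, tau_high) of the vote total triages
the dataset; removing incorrect and/or noisy items cleanses it. Multiple
rounds re-run the procedure on the survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import backends
from .backends import BackendFitError, ModelSpec, TrainedModel

VOTING_SCOPES = ("all_items", "out_of_fold")
REMOVAL_POLICIES = ("incorrect_and_noisy", "incorrect_only", "noisy_only")
CATEGORIES = ("correct", "incorrect", "noisy")


class UntrainableDatasetError(RuntimeError):
    """Raised when screening declares a dataset unsuitable for UDC."""


@dataclass
class LabeledDataset:
    """Items with unique ids, a feature matrix (or image paths), and labels.

    Labels are integers in [0, C) indexing ``class_names``. ``meta`` carries
    free-form provenance (e.g. image shape for rendered datasets, or the
    ``untrainable`` flag set when cleansing empties a class).
    """

    item_ids: np.ndarray
    labels: np.ndarray
    features: np.ndarray | None = None
    image_paths: tuple | None = None
    class_names: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.item_ids = np.asarray(self.item_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if len(self.features) != len(self.labels):
                raise ValueError("features and labels must have equal length")
        if self.features is None and self.image_paths is None:
            raise ValueError("either features or image_paths must be provided")
        if len(self.item_ids) != len(self.labels):
            raise ValueError("item_ids and labels must have equal length")
        if len(np.unique(self.item_ids)) != len(self.item_ids):
            raise ValueError("item_ids must be unique")
        if not self.class_names:
            c = int(self.labels.max()) + 1 if len(self.labels) else 0
            self.class_names = tuple(f"class_{i}" for i in range(max(c, 2)))
        self.class_names = tuple(self.class_names)
        if len(self.class_names) < 2:
            raise ValueError("at least two classes are required (C >= 2)")
        if len(self.labels) and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("labels must lie in [0, C)")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices) -> "LabeledDataset":
        """Row subset preserving order, ids and labels."""
        indices = np.asarray(indices)
        return LabeledDataset(
            item_ids=self.item_ids[indices],
            labels=self.labels[indices],
            features=None if self.features is None else self.features[indices],
            image_paths=None
            if self.image_paths is None
            else tuple(np.asarray(self.image_paths, dtype=object)[indices]),
            class_names=self.class_names,
            meta=dict(self.meta),
        )

    def with_labels(self, labels) -> "LabeledDataset":
        return replace(self, labels=np.asarray(labels, dtype=int), meta=dict(self.meta))


def default_model_specs(n: int = 3, mode: str = "feature") -> tuple[ModelSpec, ...]:
    """The reference architecture ensemble: n desk-scale surrogate backends.

    Feature mode draws from a pool of one regularized logistic regression,
    two MLP widths, and a strongly regularized logistic regression; image mode
    substitutes the random-filter convolutional backend for the first slot.
    """
    pool = [
        ModelSpec("logreg", "linear", {"C": 1.0}, seed=11),
        ModelSpec("mlp16", "mlp", {"hidden_sizes": (16,), "alpha": 1e-2}, seed=23),
        ModelSpec("mlp32", "mlp", {"hidden_sizes": (32,), "alpha": 1e-1}, seed=37),
        ModelSpec("logreg_c01", "linear", {"C": 0.1}, seed=47),
    ]
    if mode == "image":
        pool[0] = ModelSpec("convnet", "small_cnn", {}, seed=11)
    if not 1 <= n <= len(pool):
        raise ValueError(f"n must be in [1, {len(pool)}]")
    return tuple(pool[:n])


@dataclass(frozen=True)
class UDCConfig:
    """Configuration of one UDC run.

    tau_low and tau_high are fractions of the per-item vote total: items with
    s_j <= tau_low * total are triaged incorrect, s_j >= tau_high * total
    correct, the rest noisy.
    """

    model_specs: tuple = ()
    k: int = 5
    voting_scope: str = "all_items"
    tau_low: float = 0.3
    tau_high: float = 0.7
    removal_policy: str = "incorrect_and_noisy"
    rounds: int = 1
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        specs = tuple(self.model_specs) or default_model_specs(3)
        object.__setattr__(self, "model_specs", specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError(f"model spec names must be unique, got {names}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0 <= self.tau_low < self.tau_high <= 1):
            raise ValueError("require 0 <= tau_low < tau_high <= 1")
        if self.voting_scope not in VOTING_SCOPES:
            raise ValueError(f"voting_scope must be one of {VOTING_SCOPES}")
        if self.removal_policy not in REMOVAL_POLICIES:
            raise ValueError(f"removal_policy must be one of {REMOVAL_POLICIES}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")

    @property
    def n_models(self) -> int:
        return len(self.model_specs) * self.k


@dataclass
class FoldAssignment:
    """Fold index in [0, k) per item."""

    fold_of_item: np.ndarray
    k: int

    def __post_init__(self):
        self.fold_of_item = np.asarray(self.fold_of_item, dtype=int)
        counts = np.bincount(self.fold_of_item, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")


@dataclass
class VoteMatrix:
    """(n*k) x N boolean votes; entry true iff the model predicted the item's label.

    Under out_of_fold scope only held-out entries are valid; ``valid`` masks
    them and each item receives exactly n votes.
    """

    votes: np.ndarray
    model_index: tuple  # (spec_name, fold) per row
    valid: np.ndarray

    @property
    def n_items(self) -> int:
        return self.votes.shape[1]

    def votes_per_item(self) -> np.ndarray:
        return self.valid.sum(axis=0)


@dataclass
class SuccessCounts:
    """s_j per item plus the number of votes each item received."""

    s: np.ndarray
    max_votes: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=int)
        self.max_votes = np.asarray(self.max_votes, dtype=int)
        if (self.s < 0).any() or (self.s > self.max_votes).any():
            raise ValueError("success counts must satisfy 0 <= s_j <= votes cast")


@dataclass
class TriageResult:
    """Per-item triage category with the thresholds that produced it."""

    category_of_item: np.ndarray
    counts: SuccessCounts
    thresholds_used: tuple
    round_index: int = 0
    item_ids: np.ndarray | None = None

    def ids_in_category(self, category: str) -> np.ndarray:
        if self.item_ids is None:
            raise ValueError("triage has no item ids attached")
        return self.item_ids[self.category_of_item == category]

    def category_counts(self) -> dict:
        return {c: int(np.sum(self.category_of_item == c)) for c in CATEGORIES}


@dataclass
class UDCRound:
    """Audit record of one cleansing round."""

    round_index: int
    triage: TriageResult
    removed_ids: np.ndarray
    dataset_after: LabeledDataset


# ---------------------------------------------------------------------------
# operations


def assign_folds(
    dataset: LabeledDataset, k: int, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    """Partition items into k folds, stratified by class by default.

    Deterministic under seed; fold sizes within one item of N/k (stratified
    mode additionally preserves per-fold class proportions within one item).
    """
    n = dataset.n_items
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size N={n}")
    if stratified:
        counts = dataset.class_counts()
        present = np.flatnonzero(counts)
        too_small = present[counts[present] < k]
        if len(too_small):
            name = dataset.class_names[too_small[0]]
            raise ValueError(
                f"stratified folds infeasible: class {name!r} has "
                f"{counts[too_small[0]]} items < k={k}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    fold_of_item = np.empty(n, dtype=int)
    X_dummy = np.zeros((n, 1))
    for f, (_, held_out) in enumerate(splitter.split(X_dummy, dataset.labels)):
        fold_of_item[held_out] = f
    return FoldAssignment(fold_of_item=fold_of_item, k=k)


def _fit_seed(config_seed: int, spec: ModelSpec, fold: int) -> int:
    return (config_seed * 1_000_003 + spec.seed * 101 + fold) % (2**31)


def train_vote(
    dataset: LabeledDataset,
    config: UDCConfig,
    fold_assignment: FoldAssignment | None = None,
) -> VoteMatrix:
    """Fit n specs x k folds and collect per-item correctness votes.

    Each model is fitted on the k-1 folds excluding its own. Under
    ``all_items`` scope (the default, matching the procedure of applying the
    trained models back on the training data) every model votes on every
    item; under ``out_of_fold`` a model votes only on its held-out fold.
    """
    if dataset.features is None:
        raise ValueError("train_vote requires a feature matrix; preprocess images first")
    folds = fold_assignment or assign_folds(
        dataset, config.k, seed=config.seed, stratified=config.stratified
    )
    if folds.k != config.k:
        raise ValueError("fold assignment k does not match config k")
    n_rows = len(config.model_specs) * config.k
    votes = np.zeros((n_rows, dataset.n_items), dtype=bool)
    valid = np.zeros_like(votes)
    model_index = []
    row = 0
    for spec in config.model_specs:
        for f in range(config.k):
            train_mask = folds.fold_of_item != f
            try:
                model = backends.fit(
                    spec,
                    dataset.features[train_mask],
                    dataset.labels[train_mask],
                    fold_index=f,
                    fit_seed=_fit_seed(config.seed, spec, f),
                )
            except Exception as exc:
                raise BackendFitError(
                    f"backend {spec.name!r} failed on fold {f}: {exc}", spec, f
                ) from exc
            if config.voting_scope == "all_items":
                pred = backends.predict(model, dataset.features)
                votes[row] = pred == dataset.labels
                valid[row] = True
            else:
                held = ~train_mask
                pred = backends.predict(model, dataset.features[held])
                votes[row, held] = pred == dataset.labels[held]
                valid[row, held] = True
            model_index.append((spec.name, f))
            row += 1
    return VoteMatrix(votes=votes, model_index=tuple(model_index), valid=valid)


def success_counts(votes: VoteMatrix) -> SuccessCounts:
    """s_j = number of models voting the item's label correct."""
    return SuccessCounts(
        s=(votes.votes & votes.valid).sum(axis=0),
        max_votes=votes.votes_per_item(),
    )


def triage(
    counts: SuccessCounts,
    config: UDCConfig,
    round_index: int = 0,
    item_ids: np.ndarray | None = None,
) -> TriageResult:
    """Partition items by success count.

    s_j >= tau_high * votes -> correct; s_j <= tau_low * votes -> incorrect;
    otherwise noisy. Boundary items are assigned deterministically (>= / <=).
    """
    s = counts.s
    hi = config.tau_high * counts.max_votes
    lo = config.tau_low * counts.max_votes
    category = np.full(len(s), "noisy", dtype="<U9")
    category[s >= hi] = "correct"
    category[s <= lo] = "incorrect"
    return TriageResult(
        category_of_item=category,
        counts=counts,
        thresholds_used=(config.tau_low * config.n_models, config.tau_high * config.n_models),
        round_index=round_index,
        item_ids=item_ids,
    )


_POLICY_CATEGORIES = {
    "incorrect_and_noisy": ("incorrect", "noisy"),
    "incorrect_only": ("incorrect",),
    "noisy_only": ("noisy",),
}


def cleanse(
    dataset: LabeledDataset,
    triage_result: TriageResult,
    policy: str = "incorrect_and_noisy",
) -> tuple[LabeledDataset, np.ndarray]:
    """Remove items whose triage category matches the removal policy.

    Returns the cleansed dataset (ids, order and labels of survivors
    preserved) and the removed ids. If the removal empties an entire class the
    survivors are flagged untrainable (``meta['untrainable'] = True``) and a
    warning is emitted.
    """
    if policy not in _POLICY_CATEGORIES:
        raise ValueError(f"unknown removal policy {policy!r}")
    if len(triage_result.category_of_item) != dataset.n_items:
        raise ValueError("triage does not cover the dataset")
    drop = np.isin(triage_result.category_of_item, _POLICY_CATEGORIES[policy])
    cleansed = dataset.subset(np.flatnonzero(~drop))
    removed_ids = dataset.item_ids[drop]
    before = dataset.class_counts() > 0
    after = cleansed.class_counts() > 0
    emptied = np.flatnonzero(before & ~after)
    if len(emptied):
        names = [dataset.class_names[i] for i in emptied]
        cleansed.meta["untrainable"] = True
        warnings.warn(
            f"cleansing removed every item of class(es) {names}; "
            "the surviving dataset is no longer trainable",
            UserWarning,
            stacklevel=2,
        )
    return cleansed, removed_ids


def run_udc(
    dataset: LabeledDataset,
    config: UDCConfig,
    screen: bool = False,
    screen_alpha: float = 0.05,
) -> list[UDCRound]:
    """Run ``config.rounds`` rounds of UDC, each on the previous survivors.

    Each round reassigns folds (seeded from ``config.seed`` + round), retrains
    all n*k models from scratch, triages, and cleanses under the configured
    removal policy. Stops early after a round that removes nothing. With
    ``screen=True`` each round first checks that at least one backend achieves
    statistically significant above-chance validation accuracy and raises
    :class:`UntrainableDatasetError` otherwise.
    """
    from . import screening as _screening  # local import to avoid cycle

    rounds: list[UDCRound] = []
    current = dataset
    for r in range(config.rounds):
        if screen:
            report = _screening.screen_hyperparameters(
                current,
                list(config.model_specs),
                k=config.k,
                alpha=screen_alpha,
                seed=config.seed + r,
            )
            if not report.dataset_trainable:
                raise UntrainableDatasetError(
                    f"round {r}: no candidate achieves significant above-chance "
                    f"accuracy ({report.reason or 'all candidates screened out'}); "
                    "the dataset is unsuitable for UDC"
                )
        folds = assign_folds(
            current, config.k, seed=config.seed + r, stratified=config.stratified
        )
        votes = train_vote(current, config, fold_assignment=folds)
        counts = success_counts(votes)
        tri = triage(counts, config, round_index=r, item_ids=current.item_ids)
        cleansed, removed = cleanse(current, tri, config.removal_policy)
        rounds.append(
            UDCRound(round_index=r, triage=tri, removed_ids=removed, dataset_after=cleansed)
        )
        if len(removed) == 0 or cleansed.meta.get("untrainable"):
            break
        current = cleansed
    return rounds
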