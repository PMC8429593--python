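"""Classifier backends that UDC trains and votes with.

The cleansing procedure is backend-agnostic: any classifier that can be fitted
on a labeled feature matrix and asked for hard label predictions can cast
votes. At desk scale the reference backends are a regularized logistic
regression (``linear``), a small multi-layer perceptron with early stopping
(``mlp``), and a fixed-random-filter convolutional feature map over a logistic
head for image input (``small_cnn``). A ``memorize`` backend (1-nearest
neighbour) is registered for contract testing: it reproduces its training
labels exactly and marks the memorization limit of all-items voting.

Backends must stay regularized enough that a mislabeled item embedded in the
opposite class's feature cluster remains hard to fit; otherwise voting cannot
separate incorrect from correct labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from PIL import Image
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

# Standard ImageNet channel statistics used for image preprocessing.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


class DegenerateLabelsError(ValueError):
    """Raised when a fit is requested on fewer than two distinct labels."""


class BackendFitError(RuntimeError):
    """Raised when a backend fails to fit; carries (spec, fold)."""

    def __init__(self, message: str, spec: "ModelSpec", fold_index: int):
        super().__init__(message)
        self.spec = spec
        self.fold_index = fold_index


@dataclass(frozen=True)
class ModelSpec:
    """One voting-model configuration: a backend kind plus hyperparameters.

    Parameters
    ----------
    name:
        Unique identifier within a UDC configuration.
    backend_kind:
        Key into the backend registry (``linear``, ``mlp``, ``small_cnn``,
        ``memorize``).
    hyperparameters:
        Backend-specific settings, e.g. ``C`` (inverse L2 strength) for
        ``linear``; ``hidden_sizes``, ``alpha``, ``learning_rate``,
        ``max_epochs``, ``patience`` for ``mlp``; ``image_shape``,
        ``n_filters``, ``augment`` for ``small_cnn``. ``class_weight`` may be
        ``"balanced"`` (default) or ``"none"`` for any kind.
    seed:
        Base seed; combined with the fold index so each of the k fits of the
        same spec is independently seeded yet reproducible.
    """

    name: str
    backend_kind: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.backend_kind not in _REGISTRY:
            raise ValueError(
                f"unknown backend_kind {self.backend_kind!r}; "
                f"registered: {sorted(_REGISTRY)}"
            )


@dataclass
class TrainedModel:
    """A fitted backend plus its provenance and validation trace."""

    spec: ModelSpec
    fold_index: int
    fit_summary: list[float]
    estimator: object
    n_features: int

    def __post_init__(self):
        if not self.fit_summary:
            raise ValueError("fit_summary must be non-empty after fitting")


# ---------------------------------------------------------------------------
# registry

BackendBuilder = Callable[[Mapping, int, np.ndarray, np.ndarray], tuple]
_REGISTRY: dict[str, BackendBuilder] = {}


def register_backend(kind: str, builder: BackendBuilder) -> None:
    """Register a backend builder: (hyperparameters, seed, X, y) -> (estimator, fit_summary)."""
    _REGISTRY[kind] = builder


def registered_backends() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def _oversample_balanced(X: np.ndarray, y: np.ndarray, seed: int):
    """Deterministically oversample minority classes to the majority count.

    Used for backends without native class_weight support (MLP).
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    idx_parts = []
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        if cnt < target:
            extra = rng.choice(idx, size=target - cnt, replace=True)
            idx = np.concatenate([idx, extra])
        idx_parts.append(idx)
    order = np.concatenate(idx_parts)
    rng.shuffle(order)
    return X[order], y[order]


def _build_linear(hp: Mapping, seed: int, X: np.ndarray, y: np.ndarray):
    cw = None if hp.get("class_weight", "balanced") == "none" else "balanced"
    est = LogisticRegression(
        C=float(hp.get("C", 1.0)),
        max_iter=int(hp.get("max_epochs", 500)),
        class_weight=cw,
        random_state=seed,
    )
    est.fit(X, y)
    return est, [float(est.score(X, y))]


def _build_mlp(hp: Mapping, seed: int, X: np.ndarray, y: np.ndarray):
    if hp.get("class_weight", "balanced") == "balanced":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() != counts.max():
            X, y = _oversample_balanced(X, y, seed)
    est = MLPClassifier(
        hidden_layer_sizes=tuple(hp.get("hidden_sizes", (16,))),
        alpha=float(hp.get("alpha", 1e-2)),
        learning_rate_init=float(hp.get("learning_rate", 1e-2)),
        max_iter=int(hp.get("max_epochs", 200)),
        early_stopping=True,
        validation_fraction=float(hp.get("validation_fraction", 0.15)),
        n_iter_no_change=int(hp.get("patience", 10)),
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    summary = [float(v) for v in getattr(est, "validation_scores_", [])]
    if not summary:
        summary = [float(est.score(X, y))]
    return est, summary


def _infer_image_shape(dim: int) -> tuple[int, int, int]:
    side3 = round((dim / 3) ** 0.5)
    if 3 * side3 * side3 == dim:
        return (side3, side3, 3)
    side1 = round(dim**0.5)
    if side1 * side1 == dim:
        return (side1, side1, 1)
    raise ValueError(f"cannot infer an image shape from {dim} features")


class _RandomConvFeatures:
    """Fixed (untrained) random 3x3 convolution bank + ReLU + 2x2 mean pooling.

    A deterministic stand-in for a learned convolutional stem: it gives the
    logistic head translation-local texture features of the image.
    """

    def __init__(self, image_shape, n_filters: int, seed: int):
        self.image_shape = tuple(image_shape)
        h, w, c = self.image_shape
        if h < 4 or w < 4:
            raise ValueError("small_cnn needs images of at least 4x4 pixels")
        rng = np.random.default_rng(seed)
        self.filters = rng.standard_normal((n_filters, 3, 3, c)) / np.sqrt(9 * c)

    def transform(self, X: np.ndarray) -> np.ndarray:
        h, w, c = self.image_shape
        imgs = X.reshape(len(X), h, w, c)
        win = np.lib.stride_tricks.sliding_window_view(imgs, (3, 3, c), axis=(1, 2, 3))
        win = win[:, :, :, 0]  # (N, h-2, w-2, 3, 3, c)
        maps = np.einsum("nxyabc,fabc->nxyf", win, self.filters)
        np.maximum(maps, 0.0, out=maps)
        hh = (maps.shape[1] // 2) * 2
        ww = (maps.shape[2] // 2) * 2
        maps = maps[:, :hh, :ww]
        pooled = maps.reshape(len(X), hh // 2, 2, ww // 2, 2, -1).mean(axis=(2, 4))
        return pooled.reshape(len(X), -1)


def _augment_hflip(X: np.ndarray, y: np.ndarray, image_shape):
    h, w, c = image_shape
    flipped = X.reshape(len(X), h, w, c)[:, :, ::-1, :].reshape(len(X), -1)
    return np.concatenate([X, flipped]), np.concatenate([y, y])


def _build_small_cnn(hp: Mapping, seed: int, X: np.ndarray, y: np.ndarray):
    shape = tuple(hp.get("image_shape") or _infer_image_shape(X.shape[1]))
    if hp.get("augment", False):
        X, y = _augment_hflip(X, y, shape)
    conv = _RandomConvFeatures(shape, int(hp.get("n_filters", 8)), seed)
    cw = None if hp.get("class_weight", "balanced") == "none" else "balanced"
    head = LogisticRegression(
        C=float(hp.get("C", 0.1)),
        max_iter=int(hp.get("max_epochs", 300)),
        class_weight=cw,
        random_state=seed,
    )
    feats = conv.transform(X)
    head.fit(feats, y)

    class _Pipeline:
        def __init__(self, conv, head):
            self._conv, self._head = conv, head

        def predict(self, X):
            return self._head.predict(self._conv.transform(np.asarray(X, dtype=float)))

        def score(self, X, y):
            return float(np.mean(self.predict(X) == y))

    est = _Pipeline(conv, head)
    return est, [float(head.score(feats, y))]


def _build_memorize(hp: Mapping, seed: int, X: np.ndarray, y: np.ndarray):
    est = KNeighborsClassifier(n_neighbors=int(hp.get("n_neighbors", 1)))
    est.fit(X, y)
    return est, [float(est.score(X, y))]


register_backend("linear", _build_linear)
register_backend("mlp", _build_mlp)
register_backend("small_cnn", _build_small_cnn)
register_backend("memorize", _build_memorize)


# ---------------------------------------------------------------------------
# public operations


def fit(
    spec: ModelSpec,
    features: np.ndarray,
    labels: Sequence[int],
    fold_index: int = 0,
    fit_seed: int | None = None,
) -> TrainedModel:
    """Fit one backend on a feature matrix.

    Class weighting is applied whenever class counts are unbalanced (native
    ``class_weight="balanced"`` for sklearn backends, deterministic seeded
    oversampling for the MLP). Deterministic given (spec, seed, data).

    Raises
    ------
    DegenerateLabelsError
        If fewer than two distinct labels are present.
    ValueError
        If features contain non-finite values.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError(f"features must be (n_items, dim) matching {len(y)} labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(
            "degenerate labels: at least two distinct classes are required to fit"
        )
    seed = spec.seed if fit_seed is None else fit_seed
    builder = _REGISTRY[spec.backend_kind]
    estimator, summary = builder(spec.hyperparameters, int(seed) % (2**31), X, y)
    return TrainedModel(
        spec=spec,
        fold_index=fold_index,
        fit_summary=summary,
        estimator=estimator,
        n_features=X.shape[1],
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Predict hard labels; validates the feature dimension against training."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1 and X.size == 0:
        X = X.reshape(0, model.n_features)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match training dimension {model.n_features}"
        )
    if len(X) == 0:
        return np.empty(0, dtype=int)
    return np.asarray(model.estimator.predict(X), dtype=int)


def preprocess_images(
    images: Sequence,
    size: int = 224,
    flatten: bool = True,
) -> np.ndarray:
    """Resize images to ``size`` x ``size`` RGB and apply ImageNet normalization.

    Accepts PIL images, HxW(x3) uint8/float arrays, or file paths. Grayscale is
    replicated to three channels. Each channel is scaled to [0, 1], then
    normalized with means (0.485, 0.456, 0.406) and standard deviations
    (0.229, 0.224, 0.225).

    Returns an (n_items, size*size*3) array, or (n_items, size, size, 3) when
    ``flatten=False``.
    """
    mean = np.array(IMAGENET_MEAN)
    std = np.array(IMAGENET_STD)
    out = []
    for img in images:
        if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
            try:
                pil = Image.open(img)
                pil.load()
            except (OSError, FileNotFoundError) as exc:
                raise OSError(f"cannot read image file {img!r}: {exc}") from exc
        elif isinstance(img, Image.Image):
            pil = img
        else:
            arr = np.asarray(img)
            if arr.dtype != np.uint8:
                arr = np.clip(arr, 0.0, 1.0)
                arr = np.round(arr * 255).astype(np.uint8)
            pil = Image.fromarray(arr)
        pil = pil.convert("RGB").resize((size, size), Image.BILINEAR)
        arr = np.asarray(pil, dtype=float) / 255.0
        out.append((arr - mean) / std)
    stacked = (
        np.stack(out) if out else np.empty((0, size, size, 3))
    )
    return stacked.reshape(len(out), -1) if flatten else stacked
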