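"""Classifiers: SVM on reduced features, 2-D slice backends, 3-D patch CNN.

Three families of scoring models, all emitting a continuous class-1 support
in [0, 1] so that sum-rule fusion operates on commensurate values:

* :func:`train_svm` — support vector machine on reduced voxel features,
  linear kernel by default (features >> subjects), regularization C chosen
  on an inner cross-validation grid, probability-style outputs via Platt
  scaling.
* slice backends — pluggable 2-D models trained on per-slice groups of
  RGB-like images (one model per ``(approach, gap, n)`` key, never mixing
  keys).  The desk backend is a standardized regularized logistic scorer on
  flattened bands; heavier convolutional backends can be registered behind
  the same :class:`SliceBackendSpec` interface.
* :func:`train_patch_cnn` — a 3-D convolutional network trained from
  scratch on non-overlapping volume patches (labels inherited from the
  parent volume), per-volume score obtained by sum-rule merging of its
  patch scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .decomposition import RGBLikeImage
from .io_volumes import ValidationError, Volume

__all__ = [
    "ScoredPrediction",
    "SVMModel",
    "train_svm",
    "SliceBackendSpec",
    "SliceModel",
    "train_slice_model",
    "make_backend",
    "BACKENDS",
    "Patch3DSpec",
    "extract_patches_3d",
    "PatchCNNModel",
    "train_patch_cnn",
]


@dataclass
class ScoredPrediction:
    """Continuous class-1 support for one subject from one model."""

    subject_id: str
    score: float
    source: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.score) or not 0.0 <= self.score <= 1.0:
            raise ValidationError(
                f"score must be finite and in [0, 1], got {self.score}"
            )


def _check_two_classes(y: np.ndarray, min_per_class: int = 2) -> None:
    counts = np.bincount(np.asarray(y, dtype=int), minlength=2)
    if (counts < min_per_class).any():
        raise ValidationError(
            f"need >= {min_per_class} subjects per class, got counts "
            f"{counts.tolist()}"
        )


# ---------------------------------------------------------------------------
# SVM


@dataclass
class SVMModel:
    """Fitted SVM with Platt-scaled probability outputs."""

    estimator: object
    chosen_params: dict

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probabilities for a subjects x features matrix."""
        return self.estimator.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]


def _cv_auc(scores: np.ndarray, y: np.ndarray) -> float:
    from .evaluation import auc

    return auc(scores, y)


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    kernel: str = "linear",
    k_in: int = 3,
    seed: int = 0,
) -> SVMModel:
    """Train an SVM with inner-CV choice of C and calibrated scores.

    The inner stratified ``k_in``-fold loop scores each C on held-out AUC;
    the winner is refitted on all data with ``probability=True`` (Platt
    scaling), so :meth:`SVMModel.score_matrix` returns values in [0, 1]
    suitable for sum-rule fusion.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    _check_two_classes(y)
    C_grid = [float(c) for c in C_grid]
    best_C = C_grid[0]
    if len(C_grid) > 1:
        n_splits = min(k_in, int(np.bincount(y).min()))
        if n_splits >= 2:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            aucs = []
            for C in C_grid:
                fold_aucs = []
                for tr, te in cv.split(X, y):
                    m = SVC(kernel=kernel, C=C, random_state=seed)
                    m.fit(X[tr], y[tr])
                    fold_aucs.append(_cv_auc(m.decision_function(X[te]), y[te]))
                aucs.append(float(np.mean(fold_aucs)))
            best_C = C_grid[int(np.argmax(aucs))]
    calib_cv = StratifiedKFold(
        n_splits=min(3, int(np.bincount(y).min())),
        shuffle=True,
        random_state=seed,
    )
    est = CalibratedClassifierCV(
        SVC(kernel=kernel, C=best_C, random_state=seed),
        method="sigmoid",
        cv=calib_cv,
        ensemble=False,
    )
    est.fit(X, y)
    return SVMModel(estimator=est, chosen_params={"C": best_C, "kernel": kernel})


# ---------------------------------------------------------------------------
# 2-D slice backends


@dataclass(frozen=True)
class SliceBackendSpec:
    """Declaration of a 2-D slice-classifier backend.

    ``epochs``, ``learning_rate`` and ``batch_size`` parameterize
    iteratively trained backends (defaults follow the reference training
    protocol: learning rate 1e-4, mini-batches of 30, at most 20 epochs);
    the closed-form desk backend maps ``epochs`` to its iteration cap and
    ignores the rest.  ``input_size`` is the native (H, W) a backend resizes
    to, or ``None`` to accept any shape.
    """

    name: str = "linear"
    input_size: tuple[int, int] | None = None
    epochs: int = 20
    learning_rate: float = 1e-4
    batch_size: int = 30


class SliceBackend(Protocol):
    """Interface every slice backend must implement."""

    def fit(self, images: Sequence[RGBLikeImage], labels: Sequence[int], seed: int) -> None: ...

    def score_images(self, images: Sequence[RGBLikeImage]) -> np.ndarray: ...


class LinearSliceBackend:
    """Desk-scale backend: standardized L2 logistic regression on
    flattened bands.  Deterministic given the seed; probability outputs."""

    def __init__(self, spec: SliceBackendSpec):
        self.spec = spec
        self._pipe: Pipeline | None = None
        self._constant: float | None = None

    @staticmethod
    def _flatten(images: Sequence[RGBLikeImage]) -> np.ndarray:
        return np.stack([img.bands.ravel() for img in images])

    def fit(self, images, labels, seed: int = 0) -> None:
        X = self._flatten(images)
        y = np.asarray(labels, dtype=np.int64)
        _check_two_classes(y, min_per_class=1)
        if len(np.unique(y)) < 2:
            raise ValidationError("backend requires both classes present")
        self._pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    LogisticRegression(
                        C=1.0,
                        solver="liblinear",
                        random_state=seed,
                        max_iter=max(self.spec.epochs * 50, 200),
                    ),
                ),
            ]
        )
        self._pipe.fit(X, y)

    def score_images(self, images) -> np.ndarray:
        if self._pipe is None:
            raise ValidationError("backend not fitted")
        return self._pipe.predict_proba(self._flatten(images))[:, 1]


BACKENDS: dict[str, type] = {"linear": LinearSliceBackend}


def make_backend(spec: SliceBackendSpec) -> SliceBackend:
    if spec.name not in BACKENDS:
        raise ValidationError(
            f"unknown backend {spec.name!r}; registered: {sorted(BACKENDS)}"
        )
    return BACKENDS[spec.name](spec)


@dataclass
class SliceModel:
    """A backend trained on one per-slice image group."""

    key: tuple[str, int, int]
    backend: SliceBackend
    backend_name: str

    def score_images(self, images: Sequence[RGBLikeImage]) -> np.ndarray:
        for img in images:
            if img.key != self.key:
                raise ValidationError(
                    f"image key {img.key} does not match model key {self.key}"
                )
        return np.clip(self.backend.score_images(images), 0.0, 1.0)


def train_slice_model(
    images: Sequence[RGBLikeImage],
    labels: Sequence[int],
    spec: SliceBackendSpec,
    seed: int = 0,
) -> SliceModel:
    """Train one slice model on a single ``(approach, gap, n)`` group.

    Refuses mixed-key groups, duplicate subjects, and inconsistent image
    shapes: per-slice models are only ever trained on images centered on
    the same slice across subjects.
    """
    if len(images) != len(labels):
        raise ValidationError("one label per image required")
    if not images:
        raise ValidationError("empty image group")
    keys = {img.key for img in images}
    if len(keys) > 1:
        raise ValidationError(f"mixed-key group: {sorted(keys)}")
    ids = [img.subject_id for img in images]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject in slice group")
    shapes = {img.bands.shape for img in images}
    if len(shapes) > 1:
        raise ValidationError(f"inconsistent image shapes in group: {shapes}")
    backend = make_backend(spec)
    backend.fit(images, labels, seed=seed)
    return SliceModel(key=images[0].key, backend=backend, backend_name=spec.name)


# ---------------------------------------------------------------------------
# 3-D patch CNN


@dataclass(frozen=True)
class Patch3DSpec:
    """Architecture/tiling parameters of the from-scratch 3-D CNN.

    Defaults follow the full-scale configuration: 28 x 28 x 121 input
    patches, convolution and max-pooling strides of 4, pooling window at
    most 3 x 3 (x 3); desk-scale runs shrink ``patch_shape`` and strides.
    Layer sequence is fixed: conv -> ReLU -> max-pool -> fully-connected ->
    soft-max -> classification.
    """

    patch_shape: tuple[int, int, int] = (28, 28, 121)
    conv_stride: int = 4
    pool_stride: int = 4
    receptive_field: int = 3
    pool_window: int = 3
    n_filters: int = 8
    momentum: float = 0.9

    def __post_init__(self) -> None:
        if min(self.patch_shape) < self.receptive_field:
            raise ValidationError(
                "patch extents must be >= the convolution receptive field"
            )
        if self.conv_stride < 1 or self.pool_stride < 1:
            raise ValidationError("strides must be >= 1")
        if self.pool_window > 3:
            raise ValidationError("pooling window is capped at 3")


def extract_patches_3d(v: Volume, spec: Patch3DSpec) -> list[np.ndarray]:
    """Tile a volume into non-overlapping patches on a regular grid.

    The grid is anchored at index 0 on each axis; leftover voxels beyond
    the last full patch are dropped, so the patch count is
    ``prod(floor(extent / patch_extent))``.
    """
    ps = spec.patch_shape
    for axis, (extent, p) in enumerate(zip(v.shape, ps)):
        if p > extent:
            raise ValidationError(
                f"patch extent {p} exceeds volume extent {extent} on axis {axis}"
            )
    counts = [extent // p for extent, p in zip(v.shape, ps)]
    patches = []
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                patches.append(
                    v.voxels[
                        i * ps[0] : (i + 1) * ps[0],
                        j * ps[1] : (j + 1) * ps[1],
                        k * ps[2] : (k + 1) * ps[2],
                    ].copy()
                )
    return patches


@dataclass
class PatchCNNModel:
    """Trained 3-D patch CNN with sum-rule per-volume scoring."""

    spec: Patch3DSpec
    net: "object"
    chosen_params: dict = field(default_factory=dict)

    def score_patches(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        return self.net.predict_proba(np.stack(patches))[:, 1]

    def score_volume(self, v: Volume) -> float:
        """Sum-rule (mean) merge of the volume's patch scores."""
        patch_scores = self.score_patches(extract_patches_3d(v, self.spec))
        return float(np.mean(patch_scores))

    def score_volumes(self, volumes: Sequence[Volume]) -> np.ndarray:
        return np.array([self.score_volume(v) for v in volumes])


def train_patch_cnn(
    volumes: Sequence[Volume],
    labels: Sequence[int],
    spec: Patch3DSpec | None = None,
    learning_rate: float = 1e-4,
    epochs: int = 20,
    batch_size: int = 30,
    seed: int = 0,
) -> PatchCNNModel:
    """Train the from-scratch 3-D CNN on all patches of all volumes.

    Every patch inherits the label of its parent volume; optimization is
    stochastic gradient descent with momentum (default 0.9, initial
    learning rate 1e-4).  Training is bit-reproducible for a given seed on
    a single thread.
    """
    from .cnn3d import Conv3DNet

    if spec is None:
        spec = Patch3DSpec()
    y = np.asarray(labels, dtype=np.int64)
    _check_two_classes(y, min_per_class=1)
    if len(volumes) != len(y):
        raise ValidationError("one label per volume required")
    patch_list, patch_labels = [], []
    for v, lab in zip(volumes, y):
        patches = extract_patches_3d(v, spec)
        if not patches:
            raise ValidationError(f"volume {v.subject_id!r} yields no patches")
        patch_list.extend(patches)
        patch_labels.extend([lab] * len(patches))
    net = Conv3DNet(
        input_shape=spec.patch_shape,
        n_filters=spec.n_filters,
        receptive_field=spec.receptive_field,
        conv_stride=spec.conv_stride,
        pool_window=spec.pool_window,
        pool_stride=spec.pool_stride,
        seed=seed,
    )
    net.fit(
        np.stack(patch_list),
        np.asarray(patch_labels),
        learning_rate=learning_rate,
        momentum=spec.momentum,
        epochs=epochs,
        batch_size=batch_size,
    )
    return PatchCNNModel(
        spec=spec,
        net=net,
        chosen_params={
            "learning_rate": learning_rate,
            "epochs": epochs,
            "batch_size": batch_size,
            "seed": seed,
        },
    )
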