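"""Sum-rule classifier fusion: per-slice ensembles and SVM fusion.

All fusion in the package is the *sum rule*: member scores for a subject
are summed and normalized by the member count (the unweighted mean), which
is AUC-equivalent to the plain sum while keeping fused scores in [0, 1] at
every level of the tree.  Two ready-made ensembles mirror the two fused
classification systems:

* **Method #1** — fusion of two conventional-ML pipelines: Aggregate
  Selection + SVM and kernel-PLS + SVM.
* **Method #2** — ensemble of 2-D slice classifiers: one model per
  ``(backend, approach, gap, n)``; scores are fused bottom-up, slices
  first, then decomposition configurations (approach x gap), then
  backends.  A flat mean over all slice models is available as an
  alternative and coincides with the level-wise mean when level sizes are
  equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classifiers import (
    SVMModel,
    SliceBackendSpec,
    SliceModel,
    train_slice_model,
    train_svm,
)
from .decomposition import DecompositionConfig, decompose_volume, group_by_slice
from .feature_reduction import (
    AggregateSelection,
    FeatureMatrix,
    KPLSModel,
    aggregate_select,
    kpls_fit,
    kpls_transform,
)
from .io_volumes import ValidationError, Volume

__all__ = [
    "sum_rule",
    "EnsembleModel",
    "Method1Model",
    "Method2Model",
    "build_method1",
    "build_method2",
]


def sum_rule(
    score_sets: Sequence[np.ndarray] | Mapping[str, np.ndarray],
) -> np.ndarray:
    """Fuse member score vectors by the mean-normalized sum.

    All members must score the same subjects (equal-length vectors, same
    order) with values in [0, 1].  The operation is exactly commutative in
    the members (exact summation, so member order cannot perturb the last
    bit) and idempotent on identical members.
    """
    if isinstance(score_sets, Mapping):
        vectors = list(score_sets.values())
    else:
        vectors = list(score_sets)
    if not vectors:
        raise ValidationError("sum rule needs at least one member")
    arrays = [np.asarray(v, dtype=np.float64) for v in vectors]
    length = len(arrays[0])
    for a in arrays:
        if a.ndim != 1 or len(a) != length:
            raise ValidationError(
                "members must score the same subjects (equal-length vectors)"
            )
        if not np.all(np.isfinite(a)) or a.min() < 0 or a.max() > 1:
            raise ValidationError("member scores must be finite and in [0, 1]")
    stacked = np.stack(arrays)
    return np.array(
        [math.fsum(stacked[:, j]) for j in range(length)]
    ) / len(arrays)


@dataclass
class EnsembleModel:
    """Base class: a tree of trained members fused by the sum rule."""

    chosen_params: dict = field(default_factory=dict)

    def score_volumes(self, volumes: Sequence[Volume]) -> np.ndarray:
        raise NotImplementedError

    def manifest(self) -> dict:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Method #1: fusion of two SVM pipelines


def _flatten_volumes(volumes: Sequence[Volume]) -> np.ndarray:
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValidationError(f"volumes disagree in shape: {shapes}")
    return np.stack([v.voxels.ravel() for v in volumes])


@dataclass
class Method1Model(EnsembleModel):
    """Fusion of the AS+SVM and kPLS+SVM conventional-ML pipelines."""

    selection: AggregateSelection | None = None
    svm_as: SVMModel | None = None
    kpls: KPLSModel | None = None
    svm_kpls: SVMModel | None = None
    members_used: tuple[str, ...] = ("as_svm", "kpls_svm")

    def member_scores(
        self, volumes: Sequence[Volume]
    ) -> dict[str, np.ndarray]:
        X = _flatten_volumes(volumes)
        scores: dict[str, np.ndarray] = {}
        if "as_svm" in self.members_used:
            scores["as_svm"] = self.svm_as.score_matrix(
                X[:, self.selection.selected_indices]
            )
        if "kpls_svm" in self.members_used:
            scores["kpls_svm"] = self.svm_kpls.score_matrix(
                kpls_transform(self.kpls, X)
            )
        return scores

    def score_volumes(self, volumes: Sequence[Volume]) -> np.ndarray:
        return sum_rule(self.member_scores(volumes))

    def manifest(self) -> dict:
        return {
            "method": "method1",
            "members": list(self.members_used),
            "params": self.chosen_params,
        }


def build_method1(
    volumes: Sequence[Volume],
    y: Sequence[int],
    as_k: int = 500,
    kpls_h: int = 10,
    kpls_kernel: str = "rbf",
    svm_kernel: str = "linear",
    C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    k_in: int = 3,
    seed: int = 0,
    members: Sequence[str] = ("as_svm", "kpls_svm"),
    sbmlr_reg: float | Sequence[float] | None = None,
) -> Method1Model:
    """Train Method #1 on a cohort (labels already coded 0/1).

    The AS branch selects the top ``as_k`` voxel features by aggregate
    ranking and feeds them to an SVM; the kPLS branch extracts ``kpls_h``
    kernel components (capped at N-1) and feeds the component scores to a
    second SVM; the two calibrated outputs are fused by the sum rule.
    """
    X = _flatten_volumes(volumes)
    y = np.asarray(y, dtype=np.int64)
    fm = FeatureMatrix(
        X=X,
        y=y,
        feature_ids=np.arange(X.shape[1]),
        subject_ids=np.array([v.subject_id for v in volumes]),
    )
    model = Method1Model(members_used=tuple(members))
    params: dict = {}
    if "as_svm" in members:
        sel = aggregate_select(
            fm, k=min(as_k, fm.n_features), seed=seed, sbmlr_reg=sbmlr_reg
        )
        svm_as = train_svm(
            X[:, sel.selected_indices], y, C_grid=C_grid,
            kernel=svm_kernel, k_in=k_in, seed=seed,
        )
        model.selection = sel
        model.svm_as = svm_as
        params["as_svm"] = {"k": len(sel.selected_indices), **svm_as.chosen_params}
    if "kpls_svm" in members:
        h = min(kpls_h, fm.n_subjects - 1)
        kpls = kpls_fit(fm, h=h, kernel=kpls_kernel)
        svm_kpls = train_svm(
            kpls.T, y, C_grid=C_grid, kernel=svm_kernel, k_in=k_in, seed=seed
        )
        model.kpls = kpls
        model.svm_kpls = svm_kpls
        params["kpls_svm"] = {"h": kpls.h, "kernel": kpls_kernel,
                              **svm_kpls.chosen_params}
    if not params:
        raise ValidationError("at least one member pipeline required")
    model.chosen_params = params
    return model


# ---------------------------------------------------------------------------
# Method #2: per-slice ensemble over approaches, gaps and backends


@dataclass
class Method2Model(EnsembleModel):
    """Tree of per-slice models fused slices -> (approach, gap) -> backend."""

    configs: tuple[DecompositionConfig, ...] = ()
    backend_specs: tuple[SliceBackendSpec, ...] = ()
    # members[backend_name][(approach, gap)][n] -> SliceModel
    members: dict = field(default_factory=dict)
    flat: bool = False

    def _slice_scores(
        self, volumes: Sequence[Volume]
    ) -> dict[str, dict[tuple[str, int], dict[int, np.ndarray]]]:
        images = {
            cfg: [
                img for v in volumes for img in decompose_volume(v, cfg)
            ]
            for cfg in self.configs
        }
        order = [v.subject_id for v in volumes]
        out: dict = {}
        for spec in self.backend_specs:
            per_cfg: dict = {}
            for cfg in self.configs:
                groups = group_by_slice(images[cfg])
                per_slice: dict[int, np.ndarray] = {}
                cfg_members = self.members[spec.name][(cfg.approach, cfg.gap)]
                if set(groups) != {
                    (cfg.approach, cfg.gap, n) for n in cfg_members
                }:
                    raise ValidationError(
                        "test volumes produce different slice keys than "
                        "the training cohort (shape mismatch?)"
                    )
                for key, group in groups.items():
                    model = cfg_members[key[2]]
                    imgs = [group[sid] for sid in order]
                    per_slice[key[2]] = model.score_images(imgs)
                per_cfg[(cfg.approach, cfg.gap)] = per_slice
            out[spec.name] = per_cfg
        return out

    def score_volumes(self, volumes: Sequence[Volume]) -> np.ndarray:
        tree = self._slice_scores(volumes)
        if self.flat:
            leaves = [
                s
                for per_cfg in tree.values()
                for per_slice in per_cfg.values()
                for s in per_slice.values()
            ]
            return sum_rule(leaves)
        backend_scores = []
        for per_cfg in tree.values():
            cfg_scores = [
                sum_rule(list(per_slice.values()))
                for per_slice in per_cfg.values()
            ]
            backend_scores.append(sum_rule(cfg_scores))
        return sum_rule(backend_scores)

    def manifest(self) -> dict:
        return {
            "method": "method2",
            "backends": [s.name for s in self.backend_specs],
            "configs": [
                {"approach": c.approach, "gap": c.gap,
                 "stride": c.effective_stride, "n_start": c.n_start}
                for c in self.configs
            ],
            "flat": self.flat,
            "params": self.chosen_params,
        }


def build_method2(
    volumes: Sequence[Volume],
    y: Sequence[int],
    approaches: Sequence[str] = ("A", "B", "C", "D"),
    gaps: Sequence[int] = (0, 1, 2),
    backends: Sequence[SliceBackendSpec] | None = None,
    stride: int | None = None,
    seed: int = 0,
    flat: bool = False,
) -> Method2Model:
    """Train the per-slice ensemble over all requested configurations.

    One slice model is trained per ``(backend, approach, gap, n)`` on the
    group of images centered on that slice, never mixing slice keys; each
    backend sees every (approach, gap) configuration.
    """
    if backends is None:
        backends = (SliceBackendSpec(name="linear"),)
    y = np.asarray(y, dtype=np.int64)
    if len(volumes) != len(y):
        raise ValidationError("one label per volume required")
    labels_by_id = {v.subject_id: lab for v, lab in zip(volumes, y)}
    configs = tuple(
        DecompositionConfig(approach=a, gap=g, stride=stride)
        for a in approaches
        for g in gaps
    )
    members: dict = {}
    for spec in backends:
        per_cfg: dict = {}
        for cfg in configs:
            images = [
                img for v in volumes for img in decompose_volume(v, cfg)
            ]
            groups = group_by_slice(images)
            per_slice: dict[int, SliceModel] = {}
            for key in sorted(groups):
                group = groups[key]
                sids = sorted(group)
                imgs = [group[sid] for sid in sids]
                labs = [labels_by_id[sid] for sid in sids]
                per_slice[key[2]] = train_slice_model(
                    imgs, labs, spec, seed=seed
                )
            per_cfg[(cfg.approach, cfg.gap)] = per_slice
        members[spec.name] = per_cfg
    return Method2Model(
        configs=configs,
        backend_specs=tuple(backends),
        members=members,
        flat=flat,
        chosen_params={"seed": seed, "stride": stride},
    )
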