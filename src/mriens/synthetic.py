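"""Synthetic co-registered brain-like cohorts with controllable class effects.

Real cohorts for this problem come from restricted repositories, so every
pipeline stage is exercised on generated data: a smooth nonnegative
"gray-matter-like" template (shared across subjects, emulating
co-registration), per-subject additive Gaussian noise (lightly smoothed),
and, for the affected class, a fractional intensity reduction ``d`` inside
an effect region — a crude but controllable emulation of localized
atrophy.  The default effect region is the central-crop window used by the
inner-structures analysis, reflecting that the inner cerebral structures
(hippocampal region included) are affected earliest.

Generation is bit-reproducible per seed; the affected-region mask is
exported so feature-selection localization can be evaluated against it.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_volumes import (
    CohortManifest,
    ValidationError,
    Volume,
    write_manifest,
    write_volume,
)

__all__ = ["SyntheticCohortSpec", "make_template", "make_cohort", "inner_mask"]

SPACE_TAG = "synthetic-mni-like"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions of one synthetic cohort.

    ``effect_size`` is the fractional intensity reduction applied inside
    the effect region for class-1 subjects (0 = null cohort).
    ``effect_region`` is ``"inner"`` (central-crop window), ``"uniform"``
    (whole volume) or a boolean mask array.  ``inner_k`` is the central
    window width; by default it mirrors the full-scale 121 -> 100 crop
    proportion, ``round(min_extent * 100 / 121)``.
    """

    shape: tuple[int, int, int] = (40, 48, 40)
    n_per_class: int = 20
    effect_size: float = 0.3
    effect_region: object = "inner"
    noise_sd: float = 0.08
    noise_smooth: float = 0.5
    smoothing: float = 3.0
    inner_k: int | None = None
    classes: tuple[str, str] = ("CN", "AD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValidationError("effect size d must be >= 0")
        if self.n_per_class < 4:
            raise ValidationError("need >= 4 subjects per class")
        if self.noise_sd <= 0:
            raise ValidationError("noise sd must be > 0")

    @property
    def crop_k(self) -> int:
        if self.inner_k is not None:
            return self.inner_k
        return int(round(min(self.shape) * 100.0 / 121.0))


def inner_mask(shape: tuple[int, int, int], k: int) -> np.ndarray:
    """Boolean mask of the k-central-slices window (crop_inner geometry)."""
    if k > min(shape):
        raise ValidationError(f"k={k} exceeds smallest extent of {shape}")
    mask = np.zeros(shape, dtype=bool)
    window = tuple(
        slice((extent - k) // 2, (extent - k) // 2 + k) for extent in shape
    )
    mask[window] = True
    return mask


def make_template(
    shape: tuple[int, int, int],
    smoothing: float = 3.0,
    seed: int = 0,
) -> Volume:
    """Smooth gray-matter-like intensity field in [0, 1].

    Superposition of a smoothed ellipsoidal support, randomly placed
    smoothed blobs, and a smoothed random field, all with periodic
    boundary handling so that in the infinite-smoothing limit the field
    approaches its spatial mean (a constant).  Deterministic per seed.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 8:
        raise ValidationError("template shape must be >= 8 per axis")
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(
        *[np.arange(s, dtype=float) for s in shape], indexing="ij"
    )
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.42 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    ellipsoid = (r2 <= 1.0).astype(float)

    impulses = np.zeros(shape)
    # blob density fixed per unit volume so small grids do not saturate
    n_blobs = max(8, int(np.prod(shape)) // 2000)
    pts = tuple(rng.integers(0, s, size=n_blobs) for s in shape)
    amps = rng.uniform(0.3, 1.0, size=n_blobs)
    np.add.at(impulses, pts, amps)

    noise = rng.standard_normal(shape)

    field = (
        0.75 * gaussian_filter(ellipsoid, smoothing, mode="wrap")
        + 100.0 * gaussian_filter(impulses, smoothing, mode="wrap")
        + 0.10 * gaussian_filter(noise, smoothing, mode="wrap")
    )
    return Volume(
        voxels=np.clip(field, 0.0, 1.0),
        subject_id="template",
        space_tag=SPACE_TAG,
    )


def _effect_mask(spec: SyntheticCohortSpec) -> np.ndarray:
    region = spec.effect_region
    if isinstance(region, str):
        if region == "inner":
            return inner_mask(spec.shape, spec.crop_k)
        if region == "uniform":
            return np.ones(spec.shape, dtype=bool)
        raise ValidationError(f"unknown effect region {region!r}")
    mask = np.asarray(region, dtype=bool)
    if mask.shape != tuple(spec.shape):
        raise ValidationError("custom mask shape must match volume shape")
    return mask


def make_cohort(
    spec: SyntheticCohortSpec,
    out_dir: str | os.PathLike | None = None,
) -> tuple[list[Volume], CohortManifest, np.ndarray]:
    """Generate a labeled cohort (and optionally write it to disk).

    Class 0 volumes are template + noise; class 1 volumes have the effect
    region scaled by ``(1 - d)`` before noise.  All volumes share shape and
    space tag (the co-registration contract).  When ``out_dir`` is given,
    NIfTI volumes, the CSV manifest, the effect mask and a JSON spec record
    are written there.

    Returns ``(volumes, manifest, effect_mask)``.
    """
    template = make_template(spec.shape, spec.smoothing, seed=spec.seed)
    mask = _effect_mask(spec)
    rng = np.random.default_rng(spec.seed + 1)
    affected = template.voxels.copy()
    affected[mask] *= 1.0 - spec.effect_size

    volumes: list[Volume] = []
    rows = []
    for cls, base in ((0, template.voxels), (1, affected)):
        for i in range(spec.n_per_class):
            noise = gaussian_filter(
                rng.normal(0.0, spec.noise_sd, spec.shape),
                spec.noise_smooth,
                mode="wrap",
            )
            sid = f"s{cls}{i:03d}"
            label = spec.classes[cls]
            volumes.append(
                Volume(
                    voxels=base + noise,
                    subject_id=sid,
                    label=label,
                    space_tag=SPACE_TAG,
                )
            )
            rows.append({"subject_id": sid, "path": f"{sid}.nii", "label": label})
    manifest = CohortManifest(entries=pd.DataFrame(rows), task=spec.classes)

    if out_dir is not None:
        out_dir = str(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for v, row in zip(volumes, rows):
            write_volume(v, os.path.join(out_dir, row["path"]))
        write_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
        write_volume(
            Volume(voxels=mask.astype(np.float64), subject_id="effect_mask",
                   space_tag=SPACE_TAG),
            os.path.join(out_dir, "effect_mask.nii"),
        )
        record = dataclasses.asdict(spec)
        record["effect_region"] = (
            spec.effect_region
            if isinstance(spec.effect_region, str)
            else "custom"
        )
        with open(os.path.join(out_dir, "spec.json"), "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True, default=str)
    return volumes, manifest, mask


def labels_as_int(
    volumes: list[Volume], spec_or_task
) -> np.ndarray:
    """Map cohort label strings to 0/1 (class order of the task pair)."""
    if isinstance(spec_or_task, SyntheticCohortSpec):
        task = spec_or_task.classes
    else:
        task = tuple(spec_or_task)
    mapping = {task[0]: 0, task[1]: 1}
    try:
        return np.array([mapping[v.label] for v in volumes], dtype=np.int64)
    except KeyError as exc:
        raise ValidationError(f"label {exc} not in task {task}") from exc
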