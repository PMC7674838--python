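"""Decomposition of 3-D volumes into 2-D RGB-like images.

A volumetric scan is turned into a sequence of three-band 2-D images so that
3-channel 2-D classifiers can consume it: three slices at indices
``n``, ``n + gap``, ``n + 2*gap`` become the R, G and B bands.  Four
approaches select the slicing orientations:

=========  =======================================================
approach   bands (R, G, B)
=========  =======================================================
A          sagittal n, sagittal n+gap, sagittal n+2*gap
B          coronal  n, coronal  n+gap, coronal  n+2*gap
C          transaxial n, transaxial n+gap, transaxial n+2*gap
D          sagittal n, coronal n+gap, transaxial n+2*gap
=========  =======================================================

Because cohorts are co-registered, all images centered on the same slice
refer to the same anatomical coordinates across subjects; per-slice
classifier training therefore groups images by the key
``(approach, gap, n)``.

Slice indices are 0-based internally; logs and user-facing docs report
1-based ``n`` (the first slice is n=1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_volumes import ValidationError, Volume

__all__ = [
    "ORIENTATION_AXIS",
    "APPROACH_BANDS",
    "DecompositionConfig",
    "RGBLikeImage",
    "extract_slice",
    "compose_rgb",
    "anchor_indices",
    "decompose_volume",
    "group_by_slice",
    "export_png",
]

ORIENTATION_AXIS: dict[str, int] = {
    "sagittal": 0,
    "coronal": 1,
    "transaxial": 2,
}

#: orientation of the (R, G, B) bands per approach
APPROACH_BANDS: dict[str, tuple[str, str, str]] = {
    "A": ("sagittal", "sagittal", "sagittal"),
    "B": ("coronal", "coronal", "coronal"),
    "C": ("transaxial", "transaxial", "transaxial"),
    "D": ("sagittal", "coronal", "transaxial"),
}

DEFAULT_GAPS: tuple[int, ...] = (0, 1, 2)


@dataclass(frozen=True)
class DecompositionConfig:
    """Parameters of one decomposition run.

    ``stride`` is the step between consecutive anchor indices ``n``.  When
    ``None`` the default rule is used: stride 1 for gap 0 and
    ``2*gap + 1`` for gap > 0, i.e. non-overlapping slice triplets that
    together compose the volume.
    """

    approach: str
    gap: int = 0
    stride: int | None = None
    n_start: int = 0
    scale: bool = True

    def __post_init__(self) -> None:
        if self.approach not in APPROACH_BANDS:
            raise ValidationError(
                f"unknown approach {self.approach!r}; expected one of "
                f"{sorted(APPROACH_BANDS)}"
            )
        if self.gap < 0:
            raise ValidationError("gap must be non-negative")
        if self.stride is not None and self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.n_start < 0:
            raise ValidationError("n_start must be >= 0")

    @property
    def effective_stride(self) -> int:
        if self.stride is not None:
            return self.stride
        return 1 if self.gap == 0 else 2 * self.gap + 1


@dataclass
class RGBLikeImage:
    """A three-band 2-D image built from three volume slices.

    ``bands`` has shape ``(H, W, 3)`` (R, G, B along the last axis);
    ``n`` is the 0-based anchor slice index.  ``key`` uniquely identifies
    the image's slice group within a co-registered cohort.
    """

    bands: np.ndarray
    approach: str
    gap: int
    n: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3 or self.bands.shape[2] != 3:
            raise ValidationError(
                f"bands must have shape (H, W, 3), got {self.bands.shape}"
            )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.approach, self.gap, self.n)

    @property
    def r(self) -> np.ndarray:
        return self.bands[:, :, 0]

    @property
    def g(self) -> np.ndarray:
        return self.bands[:, :, 1]

    @property
    def b(self) -> np.ndarray:
        return self.bands[:, :, 2]


def extract_slice(v: Volume, orientation: str, index: int) -> np.ndarray:
    """Return the 2-D plane at ``index`` along the named orientation."""
    if orientation not in ORIENTATION_AXIS:
        raise ValidationError(
            f"unknown orientation {orientation!r}; expected one of "
            f"{sorted(ORIENTATION_AXIS)}"
        )
    axis = ORIENTATION_AXIS[orientation]
    extent = v.shape[axis]
    if not 0 <= index < extent:
        raise IndexError(
            f"{orientation} index {index} out of range [0, {extent})"
        )
    return np.take(v.voxels, index, axis=axis).copy()


def _minmax_scale(voxels: np.ndarray) -> np.ndarray:
    lo, hi = float(voxels.min()), float(voxels.max())
    if hi > lo:
        return (voxels - lo) / (hi - lo)
    return np.zeros_like(voxels)


def _pad_to(band: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad a 2-D band symmetrically up to ``shape`` (extra on the
    high-index side when the difference is odd)."""
    pads = []
    for have, want in zip(band.shape, shape):
        total = want - have
        pads.append((total // 2, total - total // 2))
    if all(p == (0, 0) for p in pads):
        return band
    return np.pad(band, pads)


def band_indices(gap: int, n: int) -> tuple[int, int, int]:
    """Slice indices of the R, G and B bands for anchor ``n``."""
    return (n, n + gap, n + 2 * gap)


def compose_rgb(v: Volume, cfg: DecompositionConfig, n: int) -> RGBLikeImage:
    """Build the RGB-like image anchored at slice ``n`` (0-based).

    With ``cfg.scale`` (the default) the volume is min-max scaled to [0, 1]
    once before slicing, so bands are commensurate across subjects for
    backends expecting bounded inputs.  On non-cubic volumes approach D
    mixes planes of different shapes; bands are zero-padded symmetrically
    to their element-wise maximum shape (a no-op on cubic volumes).
    """
    orientations = APPROACH_BANDS[cfg.approach]
    indices = band_indices(cfg.gap, n)
    for orientation, idx in zip(orientations, indices):
        extent = v.shape[ORIENTATION_AXIS[orientation]]
        if not 0 <= idx < extent:
            raise ValidationError(
                f"approach {cfg.approach}, gap {cfg.gap}, anchor n={n + 1} "
                f"(1-based): {orientation} band index {idx} out of range "
                f"[0, {extent})"
            )
    voxels = _minmax_scale(v.voxels) if cfg.scale else v.voxels
    scaled = v.with_voxels(voxels)
    bands = [
        extract_slice(scaled, orientation, idx)
        for orientation, idx in zip(orientations, indices)
    ]
    target = tuple(
        max(b.shape[d] for b in bands) for d in range(2)
    )
    bands = [_pad_to(b, target) for b in bands]
    return RGBLikeImage(
        bands=np.stack(bands, axis=-1),
        approach=cfg.approach,
        gap=cfg.gap,
        n=n,
        subject_id=v.subject_id,
    )


def anchor_indices(
    shape: Sequence[int], cfg: DecompositionConfig
) -> list[int]:
    """Valid anchor indices for a volume shape under ``cfg``.

    Depends only on the shape and (gap, stride, n_start), never on voxel
    content: co-registered subjects share the same anchor set.
    """
    orientations = APPROACH_BANDS[cfg.approach]
    anchors = []
    n = cfg.n_start
    step = cfg.effective_stride
    while True:
        ok = all(
            idx < shape[ORIENTATION_AXIS[o]]
            for o, idx in zip(orientations, band_indices(cfg.gap, n))
        )
        if not ok:
            break
        anchors.append(n)
        n += step
    return anchors


def decompose_volume(
    v: Volume, cfg: DecompositionConfig
) -> list[RGBLikeImage]:
    """Decompose a volume into its ordered RGB-like image sequence."""
    anchors = anchor_indices(v.shape, cfg)
    if not anchors:
        raise ValidationError(
            f"volume of shape {v.shape} too small for approach "
            f"{cfg.approach} with gap {cfg.gap} (no valid anchors)"
        )
    return [compose_rgb(v, cfg, n) for n in anchors]


def group_by_slice(
    images: Iterable[RGBLikeImage],
) -> dict[tuple[str, int, int], dict[str, RGBLikeImage]]:
    """Partition a cohort's images into per-slice groups.

    Returns a map from ``(approach, gap, n)`` to ``{subject_id: image}``.
    Each group must contain exactly one image per subject and all images in
    a group must share shape (the co-registration contract); training a
    per-slice model only ever sees one group.
    """
    groups: dict[tuple[str, int, int], dict[str, RGBLikeImage]] = {}
    for img in images:
        group = groups.setdefault(img.key, {})
        if img.subject_id in group:
            raise ValidationError(
                f"duplicate image for subject {img.subject_id!r} in group "
                f"{img.key}"
            )
        group[img.subject_id] = img
    subjects = None
    for key, group in groups.items():
        shapes = {g.bands.shape for g in group.values()}
        if len(shapes) > 1:
            raise ValidationError(f"group {key} mixes image shapes {shapes}")
        ids = frozenset(group)
        if subjects is None:
            subjects = ids
        elif ids != subjects:
            raise ValidationError(
                f"group {key} covers subjects {sorted(ids)}; expected "
                f"{sorted(subjects)}"
            )
    return groups


def export_png(img: RGBLikeImage, path: str) -> None:
    """Write an 8-bit RGB PNG of the image (for visual inspection only)."""
    from PIL import Image

    arr = img.bands
    lo, hi = float(arr.min()), float(arr.max())
    scaled = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    Image.fromarray((scaled * 255).astype(np.uint8), mode="RGB").save(path)
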