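"""NIfTI-1 volume I/O, cohort manifests, and inner-structure cropping.

Volumes are assumed to live in a common registration space (e.g. MNI after
co-registration), so that a given voxel index refers to the same anatomical
location in every subject of a cohort.  Axis convention throughout the
package: axis 0 = sagittal (left-right), axis 1 = coronal
(posterior-anterior), axis 2 = transaxial (inferior-superior), i.e.
RAS-ordered grids.  Files whose header orientation differs are re-indexed to
the closest canonical (RAS) orientation at load time.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "CohortManifest",
    "read_volume",
    "write_volume",
    "crop_inner",
    "read_manifest",
    "write_manifest",
    "load_cohort",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """Input violates a contract (shape, finiteness, label consistency)."""


class FormatError(ValueError):
    """File is not a parseable 3-D NIfTI-1 image."""


@dataclass
class Volume:
    """A 3-D intensity grid with identity and registration metadata.

    Parameters
    ----------
    voxels
        3-D array of finite intensities (gray-matter probabilities or raw
        intensities; dimensionless).
    subject_id
        Stable subject identifier within a cohort.
    label
        Optional binary diagnostic class tag (e.g. ``"AD"`` / ``"CN"``).
    space_tag
        Identifier of the common registration space; volumes within one
        cohort must share it for voxel indices to be comparable.
    affine
        Voxel-to-world affine carried through I/O (not used in analysis).
    """

    voxels: np.ndarray
    subject_id: str = ""
    label: str | None = None
    space_tag: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"expected a 3-D voxel grid, got {self.voxels.ndim}-D"
            )
        if min(self.voxels.shape) < 1:
            raise ValidationError("all three extents must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("voxel grid contains NaN or Inf values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """Copy of this volume with a new voxel grid, metadata preserved."""
        return dataclasses.replace(self, voxels=voxels)


@dataclass
class CohortManifest:
    """Listing of a cohort: one (subject_id, path, label) row per subject.

    ``task`` is the ordered pair of class names, e.g. ``("AD", "CN")``;
    every label must belong to it and subject ids must be unique.
    """

    entries: pd.DataFrame
    task: tuple[str, str]

    def __post_init__(self) -> None:
        required = {"subject_id", "path", "label"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        ids = self.entries["subject_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate subject ids: {dupes}")
        bad = set(self.entries["label"].unique()) - set(self.task)
        if bad:
            raise ValidationError(
                f"labels {sorted(bad)} not in task classes {self.task}"
            )

    def __len__(self) -> int:
        return len(self.entries)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a 3-D NIfTI-1 file, re-indexed to RAS axis order.

    Raises :class:`FormatError` for unparseable or non-3-D images and
    :class:`ValidationError` if the data contain NaN/Inf.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot parse {path!r} as NIfTI: {exc}") from exc
    if img.ndim != 3:
        raise FormatError(
            f"{path!r}: expected 3-D image data, got {img.ndim}-D"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    descrip = ""
    try:
        descrip = img.header["descrip"].item().decode("ascii", "ignore")
    except Exception:
        pass
    subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    if subject_id.endswith(".nii"):
        subject_id = subject_id[:-4]
    return Volume(
        voxels=data,
        subject_id=subject_id,
        space_tag=descrip,
        affine=np.asarray(img.affine),
    )


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (float64 on disk, lossless round-trip).

    The ``space_tag`` is stored in the header ``descrip`` field so it
    survives a write/read cycle.
    """
    img = nib.Nifti1Image(v.voxels, affine=v.affine)
    img.header.set_data_dtype(np.float64)
    if v.space_tag:
        img.header["descrip"] = v.space_tag.encode("ascii", "ignore")[:79]
    nib.save(img, str(path))


def crop_inner(v: Volume, k: int = 100) -> Volume:
    """Crop a volume to its ``k`` central slices on every axis.

    The window start on each axis is ``floor((extent - k) / 2)``; when
    ``extent - k`` is odd the extra voxel is dropped from the high-index
    side.  A standard post-registration 121 x 145 x 121 grid with the
    default ``k = 100`` yields the 100 x 100 x 100 inner-structures volume
    (hippocampal region included).
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    for axis, extent in enumerate(v.shape):
        if k > extent:
            raise ValidationError(
                f"k={k} exceeds extent {extent} on axis {axis}"
            )
    starts = [(extent - k) // 2 for extent in v.shape]
    window = tuple(slice(s, s + k) for s in starts)
    return v.with_voxels(v.voxels[window].copy())


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    cols = ["subject_id", "path", "label"]
    manifest.entries[cols].to_csv(path, index=False)


def read_manifest(
    path: str | os.PathLike, task: tuple[str, str] | None = None
) -> CohortManifest:
    """Read a headered CSV manifest (columns subject_id,path,label).

    If ``task`` is omitted it is inferred as the sorted pair of distinct
    labels present in the file.
    """
    entries = pd.read_csv(path, dtype={"subject_id": str, "label": str})
    if task is None:
        labels = sorted(entries["label"].dropna().unique())
        if len(labels) != 2:
            raise ValidationError(
                f"cannot infer a binary task from labels {labels}"
            )
        task = (labels[0], labels[1])
    return CohortManifest(entries=entries, task=task)


def load_cohort(
    manifest: CohortManifest, base_dir: str | os.PathLike | None = None
) -> list[Volume]:
    """Load all volumes of a manifest and enforce the co-registration contract.

    All volumes must share shape and space_tag; labels and subject ids are
    taken from the manifest (overriding anything derived from file names).
    """
    volumes: list[Volume] = []
    for row in manifest.entries.itertuples(index=False):
        path = row.path
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(str(base_dir), path)
        v = read_volume(path)
        v.subject_id = str(row.subject_id)
        v.label = str(row.label)
        volumes.append(v)
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValidationError(f"cohort volumes disagree in shape: {shapes}")
    tags = {v.space_tag for v in volumes}
    if len(tags) > 1:
        raise ValidationError(f"cohort volumes disagree in space_tag: {tags}")
    return volumes


def check_cohort(volumes: Sequence[Volume]) -> None:
    """Validate the shared-shape / shared-space contract on a volume list."""
    if not volumes:
        raise ValidationError("empty cohort")
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValidationError(f"cohort volumes disagree in shape: {shapes}")
    ids = [v.subject_id for v in volumes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject ids in cohort")
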