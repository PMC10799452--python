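"""2D training/validation/test dataset construction from labelled volumes.

A 3D volume of extent E along an axis yields floor(E / spacing) slices at
indices spacing, 2*spacing, ... (1-based; an extent of 667 with spacing 8
gives 83 slices).  Training slices are taken in the XY and YZ orientations,
validation slices in XZ, and test samples stay full 3D volumes.  The
manifest records every slice's source volume, orientation and index, so a
split is fully reproducible and leakage-checkable.

Axes are stored (Z, Y, X); an XY slice fixes Z, a YZ slice fixes X, and an
XZ slice fixes Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitConfig", "slice_indices", "extract_slices", "build_split",
           "first_half_filter", "get_slice"]

_ORIENT_AXIS = {"XY": 0, "XZ": 1, "YZ": 2}


@dataclass(frozen=True)
class SplitConfig:
    train_orientations: tuple[str, ...] = ("XY", "YZ")
    val_orientation: str = "XZ"
    train_spacing: int = 8
    val_spacing: int = 512
    volume_extent: int = 667

    def __post_init__(self):
        if self.train_spacing < 1 or self.val_spacing < 1:
            raise ValueError("spacings must be >= 1")
        if self.val_orientation in self.train_orientations:
            raise ValueError("train and validation orientations must be distinct")
        for o in (*self.train_orientations, self.val_orientation):
            if o not in _ORIENT_AXIS:
                raise ValueError(f"unknown orientation {o!r}")


def slice_indices(extent: int, spacing: int) -> np.ndarray:
    """0-based slice indices: spacing, 2*spacing, ... (count floor(extent/spacing))."""
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    return np.arange(spacing, extent + 1, spacing) - 1


def get_slice(volume: np.ndarray, orientation: str, index: int) -> np.ndarray:
    """One 2D slice of a (Z, Y, X) volume in the given orientation."""
    axis = _ORIENT_AXIS[orientation]
    return np.take(volume, index, axis=axis)


def extract_slices(
    volume: np.ndarray,
    orientation: str,
    spacing: int,
    labels: np.ndarray | None = None,
):
    """Ordered 2D slices of a volume (optionally with paired label slices).

    Returns a list of images, or a list of (image, label) pairs when
    ``labels`` is given.  A spacing beyond the axis extent yields an empty
    list.
    """
    axis = _ORIENT_AXIS[orientation]
    idx = slice_indices(volume.shape[axis], spacing)
    images = [get_slice(volume, orientation, int(i)) for i in idx]
    if labels is None:
        return images
    if labels.shape != volume.shape:
        raise ValueError("labels shape differs from volume shape")
    lab = [get_slice(labels, orientation, int(i)) for i in idx]
    return list(zip(images, lab))


def build_split(samples, config: SplitConfig) -> pd.DataFrame:
    """Slice manifest over a list of sample records.

    Each sample is a mapping with at least ``id``, ``role`` ("train" or
    "test") and ``shape``; arbitrary extra keys (style, position,
    repetition) are carried through.  Training samples contribute
    2D slices in the training orientations at ``train_spacing`` and in the
    validation orientation at ``val_spacing``; test samples contribute one
    full-volume record and no 2D slices.  Raises on split leakage
    (a sample id appearing in both roles).
    """
    roles: dict[str, str] = {}
    for s in samples:
        sid = s["id"]
        if sid in roles and roles[sid] != s["role"]:
            raise ValueError(f"split leakage: sample {sid!r} in both train and test")
        roles[sid] = s["role"]

    records = []
    for s in samples:
        shape = s["shape"]
        extra = {k: v for k, v in s.items() if k not in ("id", "role", "shape")}
        if s["role"] == "test":
            records.append({"sample_id": s["id"], "split": "test",
                            "orientation": None, "index": -1, **extra})
            continue
        for orient in config.train_orientations:
            extent = shape[_ORIENT_AXIS[orient]]
            for i in slice_indices(extent, config.train_spacing):
                records.append({"sample_id": s["id"], "split": "train",
                                "orientation": orient, "index": int(i), **extra})
        extent = shape[_ORIENT_AXIS[config.val_orientation]]
        for i in slice_indices(extent, config.val_spacing):
            records.append({"sample_id": s["id"], "split": "val",
                            "orientation": config.val_orientation,
                            "index": int(i), **extra})
    manifest = pd.DataFrame(records)
    dup = manifest[manifest["split"] != "test"].duplicated(
        subset=["sample_id", "orientation", "index"])
    if dup.any():
        raise ValueError("duplicate slices in manifest")
    return manifest


def first_half_filter(manifest: pd.DataFrame) -> pd.DataFrame:
    """Keep the first half of each sample's slice list per orientation.

    This expresses combined-fruit training sets built from half the slices
    of each orientation.  Test and validation records pass through.
    """
    def _half(group: pd.DataFrame) -> pd.DataFrame:
        if group["split"].iloc[0] != "train":
            return group
        n = len(group)
        return group.sort_values("index").head(n // 2)

    out = manifest.groupby(["sample_id", "split", "orientation"], dropna=False,
                           group_keys=False, sort=False)[manifest.columns].apply(_half)
    return out.reset_index(drop=True)
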