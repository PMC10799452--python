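"""Gradient tracking: cluster voxels by following the 3D flow field.

Every voxel whose (matrix-masked) ROI probability exceeds a threshold is
advanced along the vector field with fixed-step Euler iterations; since
the training targets point toward each cell's centre, trajectories from
all voxels of one cell converge on a common attractor.  Terminal positions
are binned to the voxel grid and bins merged by 26-connectivity (radius-1
merging), so every attractor basin becomes one label.  Labels smaller than
``min_size`` voxels are discarded.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .predict import FlowField3D

__all__ = ["mask_and_cluster", "follow_flows"]

_STRUCT26 = np.ones((3, 3, 3), bool)


def follow_flows(vectors: np.ndarray, start: np.ndarray, n_iter: int = 200,
                 step: float = 1.0, min_norm: float = 0.05) -> np.ndarray:
    """Euler-integrate points through a (3, Z, Y, X) vector field.

    The field is sampled by nearest-neighbour lookup and normalized to
    unit length per voxel, so every iteration advances by ``step`` voxels
    along the local flow direction regardless of the predicted magnitude
    (slice averaging and regression shrinkage attenuate magnitudes but
    preserve direction).  Voxels where the magnitude falls below
    ``min_norm`` are treated as stationary.  Positions are clipped to the
    volume; returns the terminal float positions.
    """
    norm = np.sqrt((vectors**2).sum(axis=0))
    unit = vectors / np.maximum(norm, 1e-12)
    unit[:, norm < min_norm] = 0.0
    shape = np.array(vectors.shape[1:])
    pos = np.asarray(start, np.float32).copy()
    upper = (shape - 1).astype(np.float32)
    for _ in range(n_iter):
        idx = np.rint(pos).astype(np.int64)
        v = unit[:, idx[:, 0], idx[:, 1], idx[:, 2]].T
        pos += step * v
        np.clip(pos, 0.0, upper, out=pos)
    return pos


def mask_and_cluster(
    field: FlowField3D,
    matrix_mask: np.ndarray,
    roi_threshold: float = 0.5,
    n_iter: int = 200,
    min_size: int = 64,
    step: float = 1.0,
) -> np.ndarray:
    """Instance labels from a 3D flow field restricted to the cell matrix.

    The ROI map is multiplied by the binary cell matrix; voxels above
    ``roi_threshold`` are tracked through the vector field and voxels
    whose trajectories terminate within one voxel of each other (connected
    components over the terminal bins) share a label.
    """
    if not np.isfinite(field.vectors).all() or not np.isfinite(field.roi).all():
        raise ValueError("non-finite values in flow field")
    mask = np.asarray(matrix_mask, bool)
    if mask.shape != field.roi.shape:
        raise ValueError("field and mask shapes disagree")
    roi = field.roi * mask
    active = roi > roi_threshold
    labels = np.zeros(mask.shape, np.int32)
    if not active.any():
        return labels
    start = np.argwhere(active).astype(np.float32)
    end = follow_flows(field.vectors, start, n_iter=n_iter, step=step)
    term = np.rint(end).astype(np.int64)
    bins = np.zeros(mask.shape, bool)
    bins[term[:, 0], term[:, 1], term[:, 2]] = True
    bin_labels, _ = ndi.label(bins, structure=_STRUCT26)
    labels[active] = bin_labels[term[:, 0], term[:, 1], term[:, 2]]
    if min_size > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_size)
        labels[np.isin(labels, small[small > 0])] = 0
    # consecutive relabel
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return remap[labels]
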