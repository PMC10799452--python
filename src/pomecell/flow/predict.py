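"""Slice-wise 2D prediction recombined into a 3D flow field.

The 2D model predicts, for every slice of all three orientations, two
in-plane gradient channels and an ROI channel.  In the (Z, Y, X) storage
convention an XY slice observes the (Y, X) components, an XZ slice the
(Z, X) components and a YZ slice the (Z, Y) components, so after running
all three stacks each 3D vector component has been observed exactly twice
and the ROI three times; recombination is the per-voxel mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FlowField3D", "predict_volume"]


@dataclass
class FlowField3D:
    """3D flow field: ``vectors`` (3, Z, Y, X) and ``roi`` (Z, Y, X) in [0, 1]."""

    vectors: np.ndarray
    roi: np.ndarray

    def validate(self) -> None:
        if self.vectors.shape[1:] != self.roi.shape:
            raise ValueError("vectors and roi shapes disagree")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite values in flow vectors")


# per orientation: (axis fixed, axes of the 2D slice in volume order)
_ORIENTS = {
    "XY": (0, (1, 2)),
    "XZ": (1, (0, 2)),
    "YZ": (2, (0, 1)),
}


def predict_volume(predict_fn, volume: np.ndarray) -> FlowField3D:
    """Run a 2D flow predictor on all three slice stacks and average.

    ``predict_fn(img2d, orientation, index)`` must return a (3, H, W)
    array: gradient along the slice's first axis, gradient along its
    second axis, and ROI probability.  Each 3D vector component is the
    mean of the two orientations observing it; the ROI is the mean of all
    three.
    """
    volume = np.asarray(volume)
    vec = np.zeros((3, *volume.shape), np.float32)
    roi = np.zeros(volume.shape, np.float32)
    for orientation, (axis, comps) in _ORIENTS.items():
        for index in range(volume.shape[axis]):
            img = np.take(volume, index, axis=axis)
            pred = np.asarray(predict_fn(img, orientation, index))
            if pred.shape != (3, *img.shape):
                raise ValueError(
                    f"predictor returned {pred.shape}, expected {(3, *img.shape)}")
            sel = [slice(None)] * 3
            sel[axis] = index
            sel = tuple(sel)
            vec[(comps[0], *sel)] += pred[0]
            vec[(comps[1], *sel)] += pred[1]
            roi[sel] += pred[2]
    vec /= 2.0
    roi /= 3.0
    field = FlowField3D(vectors=vec, roi=roi)
    field.validate()
    return field
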