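"""Flow-field training targets from instance labels.

Each 2D instance is converted into a simulated heat-diffusion field: heat
is repeatedly injected at the cell centre (the median pixel coordinate,
snapped into the mask) and diffused by neighbour averaging restricted to
the instance mask.  The two spatial gradients of the converged heat map,
unit-normalized inside the mask and zero outside, are the regression
targets; the third channel is the binary cell-interior (ROI) mask.
Following the gradients uphill from any pixel of a cell leads to that
cell's centre, which is what the 3D gradient-tracking step exploits.

The number of diffusion iterations is twice the instance's maximum
bounding-box extent, enough for the heat front to traverse any pixel of
the cell and leave a strictly monotone field along the travel direction.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["labels_to_flows", "flows3d_from_labels"]


def _diffuse(mask: np.ndarray, center: tuple[int, int], n_iter: int) -> np.ndarray:
    """Heat diffusion with source re-injection at ``center``, inside ``mask``."""
    h, w = mask.shape
    heat = np.zeros((h, w), np.float64)
    k = np.array([[0.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 0.0]]) / 5.0
    inv = np.zeros_like(heat)
    denom = ndi.convolve((mask > 0).astype(np.float64), k * 5.0, mode="constant")
    inv[mask] = 1.0 / denom[mask]
    for _ in range(n_iter):
        heat[center] += 1.0
        heat = ndi.convolve(heat, k * 5.0, mode="constant") * inv
        heat[~mask] = 0.0
    return heat


def labels_to_flows(label_slice: np.ndarray) -> np.ndarray:
    """(3, H, W) flow target of a 2D label image.

    Channels: unit gradient along axis 0, unit gradient along axis 1
    (pointing toward each instance's centre), and the binary ROI mask.
    An empty slice yields an all-zero target.
    """
    labels = np.asarray(label_slice)
    out = np.zeros((3, *labels.shape), np.float32)
    if labels.max() == 0:
        return out
    slices = ndi.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        pad_sl = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                       for s, dim in zip(sl, labels.shape))
        mask = labels[pad_sl] == lab
        coords = np.argwhere(mask)
        med = np.median(coords, axis=0)
        center = tuple(coords[np.argmin(((coords - med) ** 2).sum(axis=1))])
        diam = int(max(mask.shape))
        heat = _diffuse(mask, center, 2 * diam)
        gy, gx = np.gradient(np.log1p(heat))
        mag = np.sqrt(gy**2 + gx**2)
        mag[mag == 0] = 1.0
        gy, gx = gy / mag, gx / mag
        oy = out[0][pad_sl]
        ox = out[1][pad_sl]
        oy[mask] = gy[mask]
        ox[mask] = gx[mask]
        out[0][pad_sl] = oy
        out[1][pad_sl] = ox
        roi = out[2][pad_sl]
        roi[mask] = 1.0
        out[2][pad_sl] = roi
    return out


def flows3d_from_labels(labels3d: np.ndarray):
    """Reference 3D flow field by slice-wise targets and orientation averaging.

    Computes 2D flow targets on every XY, YZ and XZ slice of a 3D label
    volume and recombines them exactly as volume prediction does: each 3D
    vector component is the mean of the two orientation stacks that
    observe it and the ROI is the mean over all three stacks.  Used as the
    learning-free oracle for the representation + gradient-tracking round
    trip.  Returns ``(vectors, roi)`` with vectors shaped (3, Z, Y, X).
    """
    from .predict import predict_volume  # local import to avoid a cycle

    def oracle(img2d, orientation, index):
        del img2d
        if orientation == "XY":
            sl = labels3d[index]
        elif orientation == "XZ":
            sl = labels3d[:, index, :]
        else:  # YZ
            sl = labels3d[:, :, index]
        return labels_to_flows(sl)

    return predict_volume(oracle, np.zeros_like(labels3d, dtype=np.float32))
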