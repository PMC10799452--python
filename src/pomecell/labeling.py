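"""Cell-matrix and pore labelling from conventional grayscale volumes.

The conventional scan distinguishes the (bright) cell matrix from the
(dark) intercellular pore space but carries no contrast between cells.
The workflow here is: median pre-filter -> Otsu threshold -> morphological
opening -> invert to the pore space -> marker-based watershed on the
Euclidean distance transform to split the pore network into individual
pores.  The watershed marker depth ("marker extent") is selected
automatically as the candidate with the highest Calinski-Harabasz index of
the resulting voxel clustering.

Connectivity conventions: 26-connectivity for foreground components,
6-connectivity for background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball, h_maxima, local_maxima
from skimage.segmentation import watershed
from sklearn.metrics import calinski_harabasz_score

__all__ = [
    "PoreLabelingConfig",
    "otsu_binarize",
    "denoise_open",
    "pore_space",
    "watershed_by_distance",
    "label_pores",
    "select_marker_extent",
    "extract_matrix",
]

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass(frozen=True)
class PoreLabelingConfig:
    """Parameters of the matrix/pore extraction workflow."""

    opening_radius: int = 1
    candidate_marker_extents: tuple[int, ...] = (0, 1, 2, 3, 4)
    ch_subsample: int = 50_000
    median_size: int = 3  # pre-Otsu denoising filter

    def __post_init__(self):
        if len(self.candidate_marker_extents) == 0:
            raise ValueError("candidate_marker_extents must be non-empty")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")


def otsu_binarize(volume: np.ndarray) -> np.ndarray:
    """Cell-matrix mask by Otsu's threshold over a 256-bin histogram.

    The threshold maximizes the between-class variance; foreground is the
    bright class (intensities above the threshold).  Raises on a constant
    volume.
    """
    volume = np.asarray(volume)
    if volume.min() == volume.max():
        raise ValueError("degenerate histogram: volume is constant")
    thr = threshold_otsu(volume, nbins=256)
    return volume > thr


def denoise_open(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening with a ball structuring element."""
    if radius == 0:
        return np.asarray(mask, bool).copy()
    return ndi.binary_opening(np.asarray(mask, bool), structure=ball(radius))


def pore_space(matrix_mask: np.ndarray) -> np.ndarray:
    """Logical complement of the cell matrix within the sample volume."""
    return ~np.asarray(matrix_mask, bool)


def watershed_by_distance(mask: np.ndarray, marker_extent: float) -> np.ndarray:
    """Marker-based watershed on the negated distance transform of a mask.

    Markers are the regional maxima of the Euclidean distance transform
    after H-maxima suppression with depth ``marker_extent`` (extent 0 keeps
    every regional maximum).  Every foreground voxel receives exactly one
    positive label; an extent above the largest distance value leaves one
    label per connected component.  Empty masks return an empty labelling.
    """
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, np.int32)
    if not mask.any():
        return labels
    edt = ndi.distance_transform_edt(mask)
    if marker_extent > 0:
        peaks = h_maxima(edt, marker_extent, footprint=_STRUCT26)
    else:
        peaks = local_maxima(edt, connectivity=3)
    peaks &= mask
    if not peaks.any():  # all maxima suppressed
        comp, _ = ndi.label(mask, structure=_STRUCT26)
        return comp.astype(np.int32)
    markers, _ = ndi.label(peaks, structure=_STRUCT26)
    out = watershed(-edt, markers=markers, mask=mask, connectivity=1).astype(np.int32)
    # components whose maxima were all suppressed still need a label
    missing = mask & (out == 0)
    if missing.any():
        comp, n = ndi.label(missing, structure=_STRUCT26)
        out[missing] = comp[missing] + out.max()
    return out


def label_pores(pore_mask: np.ndarray, marker_extent: float) -> np.ndarray:
    """Individual pore labels by marker-based watershed (see above)."""
    return watershed_by_distance(pore_mask, marker_extent)


def _ch_score(labels: np.ndarray, subsample: int, seed: int = 0) -> float:
    """Calinski-Harabasz index of a labelling, voxel coordinates as features."""
    coords = np.argwhere(labels > 0)
    lab = labels[labels > 0]
    if coords.shape[0] > subsample:
        idx = np.random.default_rng(seed).choice(coords.shape[0], subsample, replace=False)
        coords, lab = coords[idx], lab[idx]
    if np.unique(lab).size < 2:
        return np.nan
    return float(calinski_harabasz_score(coords, lab))


def select_marker_extent(
    pore_mask: np.ndarray, config: PoreLabelingConfig
) -> tuple[int, pd.DataFrame]:
    """Pick the marker extent whose labelling maximizes the CH index.

    Every candidate extent is run through :func:`label_pores`; the
    Calinski-Harabasz index treats each pore voxel's 3D coordinates as a
    point and its pore label as its cluster (subsampled to
    ``config.ch_subsample`` voxels with a fixed seed).  Candidates whose
    labelling collapses below 2 labels score NaN; ties break toward the
    smallest extent.  Returns ``(best_extent, table)`` with one scored row
    per candidate.
    """
    extents = sorted(config.candidate_marker_extents)
    if len(extents) < 2:
        raise ValueError("need at least 2 candidate marker extents")
    rows = []
    for ext in extents:
        labels = label_pores(pore_mask, ext)
        n = int(labels.max())
        rows.append((ext, n, _ch_score(labels, config.ch_subsample)))
    table = pd.DataFrame(rows, columns=["extent", "n_labels", "ch_score"])
    if table["ch_score"].isna().all():
        raise ValueError("all candidate extents collapse below 2 labels")
    best = int(table.loc[table["ch_score"].idxmax(), "extent"])
    return best, table


def extract_matrix(volume: np.ndarray, config: PoreLabelingConfig | None = None) -> np.ndarray:
    """Full matrix extraction: median filter, Otsu, morphological opening."""
    config = config or PoreLabelingConfig()
    filtered = ndi.median_filter(volume, size=config.median_size)
    mask = otsu_binarize(filtered)
    return denoise_open(mask, config.opening_radius)
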