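"""Ground-truth cell labels from contrast-enhanced volumes.

In a contrast-enhanced scan the cell walls, contrast-agent filled pores,
vascular tissue and stone cells are all brighter than the cell interiors.
The two-step workflow removes those bright structures, watersheds what
remains into individual cells, and dilates each cell back to compensate
for the removed wall voxels — without ever letting two labels merge.

The manual steps of an interactive workflow (threshold picking, tracing of
vasculature and stone clusters) are replaced here by config thresholds and
by the generator's structure masks, so the pipeline runs unattended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.segmentation import expand_labels

from .labeling import watershed_by_distance
from .phantom import TissueMasks

__all__ = ["GTConfig", "strip_bright", "segment_gt_cells", "label_gt_cells",
           "annotate_structures"]


@dataclass(frozen=True)
class GTConfig:
    """Thresholds and sizes of the ground-truth workflow.

    ``t_high`` removes everything brighter than cell interiors (walls,
    contrast-filled pores, vasculature, stone cells); ``t_wall`` removes
    residual wall voxels before the watershed; ``t_low`` excludes the dark
    background.  Dilation is restricted so labels stay individual.
    """

    t_high: float = 200.0
    t_wall: float = 200.0
    t_low: float = 0.0
    marker_extent: float = 1.0
    dilation_radius: int = 2
    min_cell_volume: int = 64

    def __post_init__(self):
        if self.t_wall > self.t_high:
            raise ValueError("t_wall must be <= t_high")
        if self.dilation_radius < 0:
            raise ValueError("dilation_radius must be >= 0")


def strip_bright(ce_volume: np.ndarray, t_high: float, t_low: float = 0.0) -> np.ndarray:
    """Mask of cells (+ residual walls): intensity in (t_low, t_high]."""
    ce_volume = np.asarray(ce_volume)
    mask = (ce_volume <= t_high) & (ce_volume > t_low)
    if not mask.any():
        raise ValueError("threshold removes everything")
    return mask


def segment_gt_cells(mask: np.ndarray, ce_volume: np.ndarray,
                     config: GTConfig) -> np.ndarray:
    """Watershed + basin-constrained dilation of the stripped cell mask.

    Residual walls (voxels above ``t_wall``) are removed, the remainder is
    split by the marker-based watershed, labels smaller than
    ``min_cell_volume`` are discarded, and each label is dilated by up to
    ``dilation_radius`` voxels into the stripped mask.  Dilation assigns
    each recovered voxel to its nearest label, so labels never merge.
    """
    mask = np.asarray(mask, bool)
    core = mask & (np.asarray(ce_volume) <= config.t_wall)
    labels = watershed_by_distance(core, config.marker_extent)
    if labels.max() == 0:
        raise ValueError("no cells found")
    if config.min_cell_volume > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < config.min_cell_volume)
        labels[np.isin(labels, small[small > 0])] = 0
        if labels.max() == 0:
            raise ValueError("all cells below min_cell_volume")
    if config.dilation_radius > 0:
        labels = expand_labels(labels, distance=config.dilation_radius)
        labels[~mask] = 0
    # consecutive labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return remap[labels]


def label_gt_cells(ce_volume: np.ndarray, config: GTConfig | None = None) -> np.ndarray:
    """Complete workflow: strip bright structures, then segment cells."""
    config = config or GTConfig()
    mask = strip_bright(ce_volume, config.t_high, config.t_low)
    return segment_gt_cells(mask, ce_volume, config)


def annotate_structures(
    labels: np.ndarray, masks: TissueMasks
) -> tuple[np.ndarray, pd.DataFrame]:
    """Attach stone-cluster and vascular labels in dedicated ranges.

    Structure components get label ids above the cell range and are listed
    in the returned table with their class; cell labels inside structure
    masks are cleared so no voxel carries both.  The cell-label set used
    for AJI evaluation is recovered by dropping non-"cell" classes.
    """
    labels = np.asarray(labels).copy()
    struct = np.ones((3, 3, 3), bool)
    rows = [
        {"label": int(lab), "klass": "cell", "n_voxels": int(n)}
        for lab, n in zip(*np.unique(labels[labels > 0], return_counts=True))
    ]
    nxt = int(labels.max()) + 1
    for name, mask in (("stone", masks.stone), ("vascular", masks.vascular)):
        mask = np.asarray(mask, bool)
        if not mask.any():
            continue
        comp, n = ndi.label(mask, structure=struct)
        labels[mask] = 0  # structures displace any cell label
        for i in range(1, n + 1):
            sel = comp == i
            labels[sel] = nxt
            rows.append({"label": nxt, "klass": name, "n_voxels": int(sel.sum())})
            nxt += 1
    table = pd.DataFrame(rows, columns=["label", "klass", "n_voxels"])
    return labels, table


def cells_only(labels: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """Drop structure labels, keeping the cell-class labels for AJI."""
    keep = set(table.loc[table["klass"] == "cell", "label"].tolist())
    out = np.asarray(labels).copy()
    lut = np.zeros(int(out.max()) + 1, bool)
    lut[[k for k in keep if k <= out.max()]] = True
    out[~lut[out]] = 0
    return out
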