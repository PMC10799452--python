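"""Instance-segmentation evaluation with the Aggregated Jaccard Index (AJI).

The AJI compares a ground-truth label volume against a predicted label
volume.  Each ground-truth object is greedily matched to the still-unused
predicted object with the highest Jaccard index (intersection over union);
matched intersections are summed over matched unions, and every predicted
object that was never matched adds its full volume to the denominator::

    AJI = sum_i |G_i ∩ S_M(i)|  /  ( sum_i |G_i ∪ S_M(i)| + sum_{F in U} |S_F| )

so false positives, false negatives, over- and under-segmentation all pull
the score below 1.  The score is 0 when prediction and ground truth share no
voxel and 1 for a perfect match.

Matching order matters when predicted labels are contended: ground-truth
labels are visited in ascending label id, and Jaccard ties between candidate
predictions are broken toward the smaller predicted id, so the result is
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["AJIReport", "jaccard", "match_labels", "aji"]


@dataclass
class AJIReport:
    """Matching detail behind one AJI value.

    Attributes
    ----------
    pairs : pandas.DataFrame
        One row per ground-truth label: ``gt_label``, ``pred_label`` (0 if
        unmatched), ``jaccard``, ``intersection``, ``union``.
    unmatched_pred : pandas.DataFrame
        Predicted labels never chosen: ``pred_label``, ``size``.
    n_gt : int
        Number of ground-truth labels.
    aji : float
        The aggregated index, recomputable from the stored counts.
    """

    pairs: pd.DataFrame
    unmatched_pred: pd.DataFrame
    n_gt: int
    aji: float = field(default=np.nan)

    def recompute(self) -> float:
        """Re-derive the AJI from the stored per-pair counts."""
        num = float(self.pairs["intersection"].sum())
        den = float(self.pairs["union"].sum()) + float(self.unmatched_pred["size"].sum())
        return num / den if den > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "aji": self.aji,
            "n_gt": self.n_gt,
            "pairs": self.pairs.to_dict(orient="records"),
            "unmatched_pred": self.unmatched_pred.to_dict(orient="records"),
        }


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two boolean voxel sets."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard undefined for two empty voxel sets")
    return float(np.logical_and(a, b).sum() / union)


def _contingency(gt: np.ndarray, pred: np.ndarray):
    """Sparse overlap counts between gt and predicted labels plus label sizes."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    m = sparse.coo_matrix(
        (np.ones(gt.size, dtype=np.int64), (gt, pred)),
        shape=(int(gt.max()) + 1, int(pred.max()) + 1),
    ).tocsr()
    gt_sizes = np.asarray(m.sum(axis=1)).ravel()
    pred_sizes = np.asarray(m.sum(axis=0)).ravel()
    return m, gt_sizes, pred_sizes


def match_labels(gt: np.ndarray, pred: np.ndarray) -> AJIReport:
    """Greedy one-to-one matching of ground-truth to predicted labels.

    Ground-truth labels are visited in ascending id; each takes, among the
    predicted labels not yet used and overlapping it, the one with the
    highest Jaccard index (ties -> smaller predicted id).  A ground-truth
    label with no available overlapping prediction stays unmatched and
    contributes intersection 0 and union |G_i|.

    Returns an :class:`AJIReport` without the final ``aji`` value filled in
    (use :func:`aji` for the full computation).
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    if gt.min() < 0 or pred.min() < 0:
        raise ValueError("label volumes must be non-negative")

    m, gt_sizes, pred_sizes = _contingency(gt, pred)
    gt_ids = np.flatnonzero(gt_sizes)
    gt_ids = gt_ids[gt_ids > 0]
    pred_ids = np.flatnonzero(pred_sizes)
    pred_ids = pred_ids[pred_ids > 0]

    used: set[int] = set()
    rows = []
    for g in gt_ids:
        row = m.getrow(g)
        cand = row.indices
        ov = row.data
        keep = (cand > 0) & (ov > 0)
        cand, ov = cand[keep], ov[keep]
        best_j, best_p, best_i = -1.0, 0, 0
        for p, inter in zip(cand, ov):
            if int(p) in used:
                continue
            un = gt_sizes[g] + pred_sizes[p] - inter
            j = inter / un
            if j > best_j + 1e-15 or (abs(j - best_j) <= 1e-15 and p < best_p):
                best_j, best_p, best_i = j, int(p), int(inter)
        if best_p > 0:
            used.add(best_p)
            union = int(gt_sizes[g] + pred_sizes[best_p] - best_i)
            rows.append((int(g), best_p, best_j, best_i, union))
        else:
            rows.append((int(g), 0, 0.0, 0, int(gt_sizes[g])))

    pairs = pd.DataFrame(
        rows, columns=["gt_label", "pred_label", "jaccard", "intersection", "union"]
    )
    un_ids = [int(p) for p in pred_ids if int(p) not in used]
    unmatched = pd.DataFrame(
        {"pred_label": un_ids, "size": [int(pred_sizes[p]) for p in un_ids]}
    )
    return AJIReport(pairs=pairs, unmatched_pred=unmatched, n_gt=len(gt_ids))


def aji(gt: np.ndarray, pred: np.ndarray) -> tuple[float, AJIReport]:
    """Aggregated Jaccard Index of ``pred`` against ``gt``.

    Returns ``(value, report)`` where ``report`` carries the matched pairs,
    the unmatched predicted labels and the aggregate.  Raises if ``gt``
    contains no labels.
    """
    report = match_labels(gt, pred)
    if report.n_gt == 0:
        raise ValueError("ground truth contains no labels")
    report.aji = report.recompute()
    return report.aji, report
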