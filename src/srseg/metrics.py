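"""Segmentation quality metrics used to evaluate phantoms end to end."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .super_regions import boundary_map


def dice(pred_mask, truth_mask) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    denom = pred_mask.sum() + truth_mask.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pred_mask, truth_mask).sum() / denom


def per_class_dice(pred_labels, truth_labels, classes=None) -> dict:
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if classes is None:
        classes = np.unique(truth_labels)
    return {int(c): dice(pred_labels == c, truth_labels == c) for c in classes}


def boundary_recall(partition_labels, truth_labels, tolerance: int = 1) -> float:
    """Fraction of truth boundary voxels within ``tolerance`` (Chebyshev) of
    a predicted super-region boundary voxel."""
    truth_b = boundary_map(np.asarray(truth_labels))
    pred_b = boundary_map(np.asarray(partition_labels))
    if truth_b.sum() == 0:
        return 1.0
    if tolerance > 0:
        pred_b = ndimage.binary_dilation(
            pred_b, structure=np.ones((3, 3, 3), dtype=bool), iterations=tolerance)
    return float(pred_b[truth_b].sum() / truth_b.sum())


def undersegmentation_error(partition_labels, truth_labels) -> float:
    """Leak-based under-segmentation error.

    For every truth segment, each overlapping super-region contributes the
    voxels it leaks outside that segment (counted against its best-matching
    segment only); the total leak is normalised by the volume.
    """
    part = np.asarray(partition_labels).ravel()
    truth = np.asarray(truth_labels).ravel()
    n_part = int(part.max()) + 1
    n_truth = int(truth.max()) + 1
    overlap = np.zeros((n_part, n_truth), dtype=np.int64)
    np.add.at(overlap, (part, truth), 1)
    sizes = overlap.sum(axis=1)
    leak = (sizes - overlap.max(axis=1)).sum()
    return float(leak / part.size)
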