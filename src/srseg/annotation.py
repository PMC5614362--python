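"""Hierarchical annotation levels and scribble-style labelling.

An :class:`AnnotationLevel` is a voxel grid of label ids (-1 = unlabeled)
plus the label definitions.  Labels may name a parent label on an earlier
level; a child's voxels must lie inside its parent's voxels, which lets a
coarse first-pass segmentation be subdivided into finer classes.

Strokes emulate the interactive pen: a set of seed voxels with a pen
radius, applied at voxel, supervoxel or megavoxel granularity.  In the two
super-region modes every region touched by the pen footprint is labelled
wholesale, which is what makes scribble annotation fast — one click can
label thousands of similar voxels.  The pen footprint is an in-plane
(y, x) disk at each seed's slice, matching slice-wise painting.

Morphological refinement (dilation / erosion / opening / closing / fill
holes) cleans labels up after annotation or model-based commitment.  A
practical order is fill holes, then opening, then dilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

UNLABELED = -1

REFINE_METHODS = ("dilation", "erosion", "opening", "closing", "fill_holes")
REFINE_SCOPES = ("this_slice", "all_slices_2d", "whole_volume_3d")
STROKE_MODES = ("voxel", "supervoxel", "megavoxel")

DEFAULT_REFINE_RADIUS = 1
_RADIUS_RANGE = (1, 20)


@dataclass
class Label:
    id: int
    name: str
    color: str = "#ffffff"
    parent: Optional[Tuple[int, int]] = None  # (level id, label id) on an earlier level


@dataclass
class AnnotationLevel:
    id: int
    labels: List[Label] = field(default_factory=list)
    voxel_labels: np.ndarray = None

    def label(self, label_id: int) -> Label:
        for lab in self.labels:
            if lab.id == label_id:
                return lab
        raise KeyError(f"no label {label_id} in level {self.id}")

    def label_mask(self, label_id: int) -> np.ndarray:
        return self.voxel_labels == label_id

    def unlabeled_count(self) -> int:
        return int((self.voxel_labels == UNLABELED).sum())


@dataclass
class Stroke:
    level: int
    label: int
    seeds: np.ndarray  # (n, 3) voxel coordinates in ROI space
    pen_width: int = 1
    mode: str = "supervoxel"

    def __post_init__(self):
        self.seeds = np.atleast_2d(np.asarray(self.seeds, dtype=np.int64))
        if self.seeds.shape[1] != 3:
            raise ValueError("stroke seeds must be (n, 3) (z, y, x) coordinates")
        if self.pen_width < 1:
            raise ValueError(f"pen_width must be >= 1, got {self.pen_width}")
        if self.mode not in STROKE_MODES:
            raise ValueError(f"mode must be one of {STROKE_MODES}, got {self.mode!r}")


def add_level(ws) -> AnnotationLevel:
    """Append a new empty annotation level over the current ROI."""
    level_id = max((lv.id for lv in ws.levels), default=-1) + 1
    level = AnnotationLevel(
        id=level_id, labels=[],
        voxel_labels=np.full(ws.roi.shape, UNLABELED, dtype=np.int32),
    )
    ws.levels.append(level)
    return level


def add_label(level: AnnotationLevel, name: str, color: str = "#ffffff",
              parent: Optional[Tuple[int, int]] = None) -> Label:
    """Add a label to a level; ``parent`` must reference an earlier level."""
    if parent is not None and parent[0] >= level.id:
        raise ValueError(
            f"parent level {parent[0]} must come before level {level.id}"
        )
    label_id = max((lab.id for lab in level.labels), default=-1) + 1
    lab = Label(id=label_id, name=name, color=color,
                parent=tuple(parent) if parent is not None else None)
    level.labels.append(lab)
    return lab


def _disk_offsets(radius: int) -> np.ndarray:
    """(n, 3) offsets of an in-plane disk of the given radius."""
    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy ** 2 + dx ** 2 <= r ** 2
    dy, dx = dy[keep], dx[keep]
    return np.stack([np.zeros_like(dy), dy, dx], axis=1)


def _stroke_footprint(stroke: Stroke, shape) -> np.ndarray:
    """Boolean grid of all voxels covered by the pen along the stroke."""
    fp = np.zeros(shape, dtype=bool)
    offsets = _disk_offsets(stroke.pen_width)  # pen_width is the disk radius
    pts = (stroke.seeds[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    valid = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
    pts = pts[valid]
    fp[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return fp


def _parent_mask(ws, level: AnnotationLevel, label: Label):
    if label.parent is None:
        return None
    plevel = ws.level(label.parent[0])
    return plevel.label_mask(label.parent[1])


def annotate(ws, stroke: Stroke) -> dict:
    """Apply a stroke; returns {'labeled': n, 'rejected': m}.

    ``rejected`` counts voxels the stroke would have claimed but that fall
    outside the label's parent region (when a parent is set).  Later strokes
    overwrite earlier ones (last stroke wins).
    """
    level = ws.level(stroke.level)
    label = level.label(stroke.label)
    shape = level.voxel_labels.shape
    if np.any(stroke.seeds < 0) or np.any(stroke.seeds >= np.asarray(shape)):
        raise ValueError("stroke seeds outside the ROI")

    fp = _stroke_footprint(stroke, shape)
    if stroke.mode == "voxel":
        target = fp
    else:
        if ws.supervoxels is None:
            raise ValueError("supervoxel/megavoxel stroke requires a supervoxel partition")
        sv = ws.supervoxels.labels
        touched = np.unique(sv[fp])
        if stroke.mode == "megavoxel":
            if ws.megavoxels is None:
                raise ValueError("megavoxel stroke requires a megavoxel partition")
            mv = ws.megavoxels.sv_to_mv
            touched_mv = np.unique(mv[touched])
            target = np.isin(mv[sv], touched_mv)
        else:
            target = np.isin(sv, touched)

    rejected = 0
    pmask = _parent_mask(ws, level, label)
    if pmask is not None:
        rejected = int((target & ~pmask).sum())
        target = target & pmask
    level.voxel_labels[target] = label.id
    return {"labeled": int(target.sum()), "rejected": rejected}


# ---------------------------------------------------------------------------
# morphological refinement


def _ball(radius: int, ndim: int) -> np.ndarray:
    grids = np.mgrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    return (grids ** 2).sum(axis=0) <= radius ** 2


def _refine_mask(mask: np.ndarray, method: str, selem: np.ndarray) -> np.ndarray:
    if method == "dilation":
        return ndimage.binary_dilation(mask, structure=selem)
    if method == "erosion":
        return ndimage.binary_erosion(mask, structure=selem)
    if method == "opening":
        return ndimage.binary_opening(mask, structure=selem)
    if method == "closing":
        return ndimage.binary_closing(mask, structure=selem)
    if method == "fill_holes":
        return ndimage.binary_fill_holes(mask)
    raise ValueError(f"unknown refinement method {method!r}; use one of {REFINE_METHODS}")


def refine_label(ws, level_id: int, label_id: int, method: str,
                 radius: int = DEFAULT_REFINE_RADIUS, scope: str = "all_slices_2d",
                 slice_index: Optional[int] = None) -> dict:
    """Morphologically refine one label's mask in place.

    The structuring element is a discrete ball (disk for the 2D scopes) of
    the given radius.  Voxels gained by dilation / closing / fill-holes only
    claim unlabeled voxels or voxels of this same label — other labels are
    never overwritten — and stay inside the parent label when one is set.
    Voxels lost by erosion / opening become unlabeled.
    """
    if method not in REFINE_METHODS:
        raise ValueError(f"unknown refinement method {method!r}; use one of {REFINE_METHODS}")
    if scope not in REFINE_SCOPES:
        raise ValueError(f"unknown scope {scope!r}; use one of {REFINE_SCOPES}")
    if not (_RADIUS_RANGE[0] <= radius <= _RADIUS_RANGE[1]):
        raise ValueError(f"radius must be in {_RADIUS_RANGE}, got {radius}")
    level = ws.level(level_id)
    label = level.label(label_id)
    mask = level.label_mask(label_id)

    if scope == "whole_volume_3d":
        refined = _refine_mask(mask, method, _ball(radius, 3))
    else:
        selem = _ball(radius, 2)
        refined = mask.copy()
        if scope == "this_slice":
            if slice_index is None:
                raise ValueError("scope 'this_slice' needs slice_index")
            refined[slice_index] = _refine_mask(mask[slice_index], method, selem)
        else:
            for z in range(mask.shape[0]):
                refined[z] = _refine_mask(mask[z], method, selem)

    gained = refined & ~mask
    lost = mask & ~refined
    # growth never overwrites other labels ...
    gained &= level.voxel_labels == UNLABELED
    # ... and never escapes the parent label
    pmask = _parent_mask(ws, level, label)
    if pmask is not None:
        gained &= pmask
    level.voxel_labels[gained] = label_id
    level.voxel_labels[lost] = UNLABELED
    return {"gained": int(gained.sum()), "lost": int(lost.sum())}


def load_strokes(path) -> List[Stroke]:
    """Read strokes from a JSON sidecar (a list of stroke records)."""
    import json

    with open(path) as f:
        records = json.load(f)
    return [Stroke(level=r["level"], label=r["label"], seeds=np.asarray(r["seeds"]),
                   pen_width=r.get("pen_width", 1), mode=r.get("mode", "supervoxel"))
            for r in records]
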