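"""Object-level analysis of a segmentation.

``extract_objects`` decomposes the selected labels of an annotation level
into connected components (26-connectivity by default, so diagonally
touching organelle blobs stay whole) and measures each object against a
query channel: average intensity, intensity variance/sd, voxel and
calibrated volume, centroid, bounding box and per-axis extent.  Objects can
then be classified by ordered rule lists ("volume_voxels > 100", "between"
ranges, ...) into named classes, saved back to an empty annotation level,
and summarised as long-format tables and pairwise scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotation import UNLABELED, AnnotationLevel, add_label

MEASURES = (
    "average_intensity", "intensity_sd", "intensity_var",
    "volume_voxels", "volume_calibrated",
    "centroid_z", "centroid_y", "centroid_x",
    "extent_z", "extent_y", "extent_x",
)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegObject:
    id: int
    source_label: int
    mask_slices: tuple  # bounding-box slices into the level grid
    mask: np.ndarray  # boolean grid within the bounding box
    measures: dict


@dataclass
class Rule:
    measure: str
    comparator: str  # '<' '<=' '>' '>=' 'between'
    threshold: float = None
    threshold_hi: float = None

    def holds(self, measures: dict) -> bool:
        if self.measure not in measures:
            raise KeyError(f"rule references unknown measure {self.measure!r}")
        v = measures[self.measure]
        if self.comparator == "<":
            return v < self.threshold
        if self.comparator == "<=":
            return v <= self.threshold
        if self.comparator == ">":
            return v > self.threshold
        if self.comparator == ">=":
            return v >= self.threshold
        if self.comparator == "between":
            return self.threshold <= v <= self.threshold_hi
        raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass
class RuleLabel:
    name: str
    color: str = "#ffffff"
    rules: List[Rule] = field(default_factory=list)  # conjunctive
    is_others: bool = False


def extract_objects(level: AnnotationLevel, label_ids: Sequence[int],
                    query_channel, connectivity: int = 26,
                    voxel_size=(1.0, 1.0, 1.0)) -> List[SegObject]:
    """Connected components per selected label, pooled, with measures.

    Components are computed within each label separately, so touching
    objects carrying different labels stay distinct.  Intensity measures
    are taken over ``query_channel``; ``voxel_size`` (dz, dy, dx) scales
    ``volume_calibrated``.
    """
    label_ids = list(label_ids)
    if not label_ids:
        raise ValueError("extract_objects needs at least one label")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    grid = np.asarray(getattr(query_channel, "data", query_channel), dtype=np.float64)
    if grid.shape != level.voxel_labels.shape:
        raise ValueError("query channel extent does not match the level")
    vz, vy, vx = voxel_size
    voxel_volume = float(vz * vy * vx)

    objects = []
    oid = 0
    for lid in label_ids:
        comp, ncomp = ndimage.label(level.label_mask(lid),
                                    structure=_STRUCTURES[connectivity])
        boxes = ndimage.find_objects(comp)
        for c in range(1, ncomp + 1):
            slc = boxes[c - 1]
            mask = comp[slc] == c
            vals = grid[slc][mask]
            n = int(mask.sum())
            coords = np.nonzero(mask)
            centroid = tuple(float(coords[a].mean() + slc[a].start) for a in range(3))
            extents = tuple(int(coords[a].max() - coords[a].min() + 1) for a in range(3))
            measures = {
                "average_intensity": float(vals.mean()),
                "intensity_sd": float(vals.std()),
                "intensity_var": float(vals.var()),
                "volume_voxels": n,
                "volume_calibrated": n * voxel_volume,
                "centroid_z": centroid[0],
                "centroid_y": centroid[1],
                "centroid_x": centroid[2],
                "extent_z": extents[0],
                "extent_y": extents[1],
                "extent_x": extents[2],
                "bbox": tuple((s.start, s.stop) for s in slc),
            }
            objects.append(SegObject(id=oid, source_label=lid, mask_slices=slc,
                                     mask=mask, measures=measures))
            oid += 1
    return objects


def apply_split(objects: List[SegObject], rule_labels: List[RuleLabel]) -> dict:
    """Assign each object to the first rule label whose rules all hold.

    Unmatched objects fall to the ``is_others`` label if one exists, else
    stay unclassified (class None).  Returns {object id: class name or None}.
    """
    others = [rl for rl in rule_labels if rl.is_others]
    if len(others) > 1:
        raise ValueError("at most one 'others' label is allowed")
    others_name = others[0].name if others else None
    assignment = {}
    for obj in objects:
        cls = None
        for rl in rule_labels:
            if rl.is_others:
                continue
            if all(rule.holds(obj.measures) for rule in rl.rules):
                cls = rl.name
                break
        if cls is None:
            cls = others_name
        assignment[obj.id] = cls
    return assignment


def save_split(assignment: dict, objects: List[SegObject],
               target_level: AnnotationLevel, rule_labels: List[RuleLabel]) -> AnnotationLevel:
    """Write the per-class voxel labels of a split into an empty level."""
    if (target_level.voxel_labels != UNLABELED).any() or target_level.labels:
        raise ValueError(f"target level {target_level.id} is not empty")
    name_to_id = {}
    for rl in rule_labels:
        lab = add_label(target_level, rl.name, rl.color)
        name_to_id[rl.name] = lab.id
    by_id = {obj.id: obj for obj in objects}
    for oid, cls in assignment.items():
        if cls is None:
            continue
        obj = by_id[oid]
        view = target_level.voxel_labels[obj.mask_slices]
        view[obj.mask] = name_to_id[cls]
    return target_level


def label_statistics(objects: List[SegObject], measures: Sequence[str],
                     assignment: Optional[dict] = None,
                     csv_path=None, plot_dir=None, plot_format: str = "png"):
    """Long-format measure table plus all pairwise measure combinations.

    Returns ``(table, pairs)`` where ``table`` has one row per object and
    measure and ``pairs`` lists the k(k-1)/2 measure pairs.  ``csv_path``
    exports the table as delimited text; ``plot_dir`` writes one scatter
    plot per pair.
    """
    measures = list(measures)
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}; use one of {MEASURES}")
    rows = []
    for obj in objects:
        cls = assignment.get(obj.id) if assignment else None
        for m in measures:
            rows.append({"object_id": obj.id, "class": cls,
                         "measure": m, "value": obj.measures[m]})
    table = pd.DataFrame(rows, columns=["object_id", "class", "measure", "value"])
    pairs = list(combinations(measures, 2))

    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if plot_dir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_dir = Path(plot_dir)
        plot_dir.mkdir(parents=True, exist_ok=True)
        wide = table.pivot(index="object_id", columns="measure", values="value")
        classes = {obj.id: (assignment.get(obj.id) if assignment else None)
                   for obj in objects}
        for mx, my in pairs:
            fig, ax = plt.subplots(figsize=(4, 4))
            for cls in sorted({c for c in classes.values()}, key=str):
                ids = [oid for oid, c in classes.items() if c == cls]
                ax.scatter(wide.loc[ids, mx], wide.loc[ids, my],
                           label=str(cls), s=18)
            ax.set_xlabel(mx)
            ax.set_ylabel(my)
            if assignment:
                ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(plot_dir / f"{mx}_vs_{my}.{plot_format}")
            plt.close(fig)
    return table, pairs


def rules_from_config(config: list) -> List[RuleLabel]:
    """Build rule labels from a JSON/YAML-style list of mappings."""
    out = []
    for entry in config:
        rules = [Rule(measure=r["measure"], comparator=r["comparator"],
                      threshold=r.get("threshold"),
                      threshold_hi=r.get("threshold_hi"))
                 for r in entry.get("rules", [])]
        out.append(RuleLabel(name=entry["name"], color=entry.get("color", "#ffffff"),
                             rules=rules, is_others=entry.get("is_others", False)))
    return out
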