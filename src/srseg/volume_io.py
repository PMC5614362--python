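"""Workspace management and volume I/O.

A :class:`Workspace` bundles a loaded tomogram, the active region of
interest (ROI), the derived feature channels, annotation levels and the
super-region partitions.  Volumes are held in (z, y, x) axis order; HDF5,
MRC (modes 0/1/2) and single/multi-page TIFF stacks are supported for both
loading and export.

All coordinates are 0-based and ROI bounds are half-open intervals, so an
ROI of ``(0, 8, 0, 8, 0, 8)`` on an 8x8x8 volume covers the whole volume.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import tifffile

from . import mrc

_ORIENTATIONS = {"zyx": (0, 1, 2), "zxy": (0, 2, 1), "yzx": (1, 0, 2),
                 "yxz": (1, 2, 0), "xzy": (2, 0, 1), "xyz": (2, 1, 0)}

EXPORT_OUTPUTS = ("raw_data", "raw_annotations", "segmentation_masks", "masked_data")
EXPORT_FORMATS = ("hdf5", "mrc", "tiff")

# on-disk workspace schema version (group names are an artifact of this
# package, not of any acquisition standard)
_SCHEMA_VERSION = 1


@dataclass
class Volume:
    """A 3D scalar grid in (z, y, x) order with its load-time orientation tag."""

    data: np.ndarray
    orientation: str = "zyx"

    @property
    def shape(self):
        return self.data.shape

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")


@dataclass
class ROI:
    """Half-open (z, y, x) bounds selecting the working sub-volume."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int
    selected: bool = True

    @property
    def bounds(self):
        return (self.z0, self.z1, self.y0, self.y1, self.x0, self.x1)

    @property
    def shape(self):
        return (self.z1 - self.z0, self.y1 - self.y0, self.x1 - self.x0)

    @property
    def slices(self):
        return (slice(self.z0, self.z1), slice(self.y0, self.y1), slice(self.x0, self.x1))

    def validate(self, volume_shape):
        for axis, (a0, a1, ext) in enumerate(zip(self.bounds[::2], self.bounds[1::2], volume_shape)):
            if not (0 <= a0 < a1 <= ext):
                raise ValueError(
                    f"ROI bounds ({a0}, {a1}) invalid on axis {axis} with extent {ext}"
                )


@dataclass
class Workspace:
    """A volume plus everything derived from it during a segmentation session."""

    volume: Volume
    roi: ROI = None
    channels: dict = field(default_factory=dict)  # name -> FeatureChannel
    levels: list = field(default_factory=list)  # AnnotationLevel
    supervoxels: Optional[object] = None
    megavoxels: Optional[object] = None
    storage_dir: Optional[Path] = None

    def __post_init__(self):
        if self.roi is None:
            nz, ny, nx = self.volume.shape
            self.roi = ROI(0, nz, 0, ny, 0, nx)
        if self.storage_dir is not None:
            self.storage_dir = Path(self.storage_dir)

    @property
    def roi_data(self) -> np.ndarray:
        """Raw data restricted to the active ROI."""
        return self.volume.data[self.roi.slices]

    def channel_data(self, name: str) -> np.ndarray:
        """ROI-shaped grid for ``name``: a channel, or the raw data itself."""
        if name in ("__data__", "raw", "raw_data"):
            return self.roi_data
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name].data

    def level(self, level_id: int):
        for lv in self.levels:
            if lv.id == level_id:
                return lv
        raise KeyError(f"no annotation level with id {level_id}")

    # -- persistence ------------------------------------------------------

    def save(self, path=None) -> Path:
        """Persist the workspace to a single HDF5 file."""
        if path is None:
            if self.storage_dir is None:
                raise ValueError("no path given and workspace has no storage_dir")
            self.storage_dir.mkdir(parents=True, exist_ok=True)
            path = self.storage_dir / "workspace.h5"
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = _SCHEMA_VERSION
            f.attrs["orientation"] = self.volume.orientation
            f.attrs["roi"] = json.dumps(self.roi.bounds)
            f.create_dataset("data", data=self.volume.data)
            ch = f.create_group("channels")
            for name, channel in self.channels.items():
                ds = ch.create_dataset(name, data=channel.data)
                ds.attrs["operator"] = channel.operator
                ds.attrs["source"] = channel.source
                ds.attrs["params"] = json.dumps(channel.params)
            lv = f.create_group("levels")
            for level in self.levels:
                g = lv.create_group(str(level.id))
                g.create_dataset("voxel_labels", data=level.voxel_labels)
                g.attrs["labels"] = json.dumps(
                    [dataclasses.asdict(lab) for lab in level.labels]
                )
            if self.supervoxels is not None:
                sv = f.create_group("supervoxels")
                sv.create_dataset("labels", data=self.supervoxels.labels)
                sv.attrs["params"] = json.dumps(self.supervoxels.params)
            if self.megavoxels is not None:
                mv = f.create_group("megavoxels")
                mv.create_dataset("sv_to_mv", data=self.megavoxels.sv_to_mv)
                mv.attrs["params"] = json.dumps(self.megavoxels.params)
        return path

    @classmethod
    def load(cls, path) -> "Workspace":
        from .annotation import AnnotationLevel, Label
        from .feature_channels import FeatureChannel
        from .super_regions import MegavoxelPartition, SupervoxelPartition

        path = Path(path)
        with h5py.File(path, "r") as f:
            volume = Volume(f["data"][()], orientation=str(f.attrs["orientation"]))
            ws = cls(volume=volume, storage_dir=path.parent)
            ws.roi = ROI(*json.loads(f.attrs["roi"]))
            for name, ds in f["channels"].items():
                ws.channels[name] = FeatureChannel(
                    name=name,
                    source=str(ds.attrs["source"]),
                    operator=str(ds.attrs["operator"]),
                    params=json.loads(ds.attrs["params"]),
                    data=ds[()],
                )
            for key in sorted(f["levels"], key=int):
                g = f["levels"][key]
                labels = [Label(**d) for d in json.loads(g.attrs["labels"])]
                for lab in labels:
                    if lab.parent is not None:
                        lab.parent = tuple(lab.parent)
                ws.levels.append(
                    AnnotationLevel(id=int(key), labels=labels,
                                    voxel_labels=g["voxel_labels"][()])
                )
            if "supervoxels" in f:
                labels = f["supervoxels"]["labels"][()]
                ws.supervoxels = SupervoxelPartition(
                    labels=labels, n_regions=int(labels.max()) + 1,
                    params=json.loads(f["supervoxels"].attrs["params"]),
                )
            if "megavoxels" in f:
                sv_to_mv = f["megavoxels"]["sv_to_mv"][()]
                ws.megavoxels = MegavoxelPartition(
                    sv_to_mv=sv_to_mv, n_regions=int(sv_to_mv.max()) + 1,
                    params=json.loads(f["megavoxels"].attrs["params"]),
                )
        return ws


# ---------------------------------------------------------------------------
# loading


def _read_hdf5(path, dataset=None):
    with h5py.File(path, "r") as f:
        if dataset is not None:
            if dataset not in f:
                raise ValueError(f"{path}: no dataset named {dataset!r}")
            return f[dataset][()]
        found = []

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset) and obj.ndim == 3:
                found.append(name)

        f.visititems(visit)
        if not found:
            raise ValueError(f"{path}: no 3D dataset found")
        if len(found) > 1:
            raise ValueError(
                f"{path}: ambiguous HDF5 file with multiple 3D datasets {found}; "
                "pass dataset= explicitly"
            )
        return f[found[0]][()]


def load_volume(path, orientation: str = "zyx", dataset: Optional[str] = None,
                impute_nonfinite: bool = False, storage_dir=None) -> Workspace:
    """Load an HDF5 / MRC / TIFF-stack volume into a fresh workspace.

    ``orientation`` names the axis order of the file ("zyx" means the file is
    already slice-major); the volume is permuted to internal (z, y, x) order.
    Non-finite voxels raise by default; with ``impute_nonfinite=True`` they
    are replaced by the median of the finite voxels.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}; use one of {sorted(_ORIENTATIONS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        data = _read_hdf5(path, dataset)
    elif suffix in (".mrc", ".map", ".rec"):
        data = mrc.read(path)
    elif suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")
    data = np.asarray(data)
    if data.ndim == 2:  # single-page TIFF is not a volume
        raise ValueError(f"{path}: dataset is 2D, expected a 3D volume")
    if data.ndim != 3:
        raise ValueError(f"{path}: dataset is {data.ndim}D, expected 3D")
    # permute the file's axis order to (z, y, x)
    data = np.transpose(data, _ORIENTATIONS[orientation])
    if not np.isfinite(data).all():
        if not impute_nonfinite:
            raise ValueError(
                f"{path}: volume contains non-finite voxels; "
                "pass impute_nonfinite=True to replace them with the median"
            )
        data = data.astype(np.float64, copy=True)
        bad = ~np.isfinite(data)
        data[bad] = np.median(data[~bad])
    return Workspace(volume=Volume(np.ascontiguousarray(data), orientation=orientation),
                     storage_dir=storage_dir)


def set_roi(ws: Workspace, bounds) -> ROI:
    """Select a new ROI; invalidates every product computed for the old one."""
    roi = ROI(*[int(b) for b in bounds])
    roi.validate(ws.volume.shape)
    if roi.bounds != ws.roi.bounds:
        # products are tied to the ROI extent: drop them
        ws.channels.clear()
        ws.levels.clear()
        ws.supervoxels = None
        ws.megavoxels = None
    ws.roi = roi
    return roi


# ---------------------------------------------------------------------------
# export


def _write_grid(path, data, fmt):
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=data)
    elif fmt == "mrc":
        mrc.write(path, data)
    elif fmt == "tiff":
        tifffile.imwrite(path, data)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _ext(fmt):
    return {"hdf5": ".h5", "mrc": ".mrc", "tiff": ".tif"}[fmt]


def load_grid(path, dataset=None) -> np.ndarray:
    """Re-load a grid written by :func:`export` (any supported format)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return _read_hdf5(path, dataset)
    if suffix in (".mrc", ".map", ".rec"):
        return mrc.read(path)
    return tifffile.imread(path)


def export(ws: Workspace, output: str, fmt: str, out_dir,
           levels=None, scale: Optional[float] = None, invert: bool = False,
           mask_source: Optional[str] = None) -> list:
    """Write ROI data, annotations, per-label masks or masked data to files.

    Returns the list of written paths.  ``scale`` multiplies and ``invert``
    maps ``x -> max - x`` (both applied before writing; invert after scale).
    ``levels`` selects annotation levels by id for the annotation-derived
    outputs (default: all).  ``mask_source`` names the channel/dataset the
    label masks are applied to for ``masked_data``.
    """
    if output not in EXPORT_OUTPUTS:
        raise ValueError(f"unknown output {output!r}; use one of {EXPORT_OUTPUTS}")
    fmt = fmt.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; use one of {EXPORT_FORMATS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def transform(arr):
        arr = np.asarray(arr, dtype=np.float32)
        if scale is not None:
            arr = arr * np.float32(scale)
        if invert:
            arr = arr.max() - arr
        return arr

    written = []
    if output == "raw_data":
        data = ws.roi_data
        if scale is not None or invert:
            data = transform(data)
        path = out_dir / f"raw_data{_ext(fmt)}"
        _write_grid(path, data, fmt)
        return [path]

    selected = ws.levels if levels is None else [ws.level(i) for i in levels]
    if output in ("raw_annotations", "segmentation_masks") and not selected:
        raise ValueError("no annotation level selected for export")

    if output == "raw_annotations":
        for level in selected:
            path = out_dir / f"annotations_level{level.id}{_ext(fmt)}"
            # integer label ids preserved (MRC uses int16 mode 1)
            labels = level.voxel_labels.astype(np.int16 if fmt == "mrc" else np.int32)
            _write_grid(path, labels, fmt)
            written.append(path)
        return written

    if output == "segmentation_masks":
        for level in selected:
            for lab in level.labels:
                mask = (level.voxel_labels == lab.id).astype(np.uint8)
                arr = transform(mask) if (scale is not None or invert) else mask
                path = out_dir / f"mask_level{level.id}_label{lab.id}{_ext(fmt)}"
                _write_grid(path, arr, fmt)
                written.append(path)
        return written

    # masked_data
    if mask_source is None:
        raise ValueError("masked_data export needs mask_source (dataset to mask)")
    target = ws.channel_data(mask_source)
    if not selected:
        raise ValueError("no annotation level selected for export")
    for level in selected:
        for lab in level.labels:
            mask = level.voxel_labels == lab.id
            arr = np.where(mask, target, 0).astype(np.float32)
            if scale is not None or invert:
                arr = transform(arr)
            path = out_dir / f"masked_level{level.id}_label{lab.id}{_ext(fmt)}"
            _write_grid(path, arr, fmt)
            written.append(path)
    return written
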