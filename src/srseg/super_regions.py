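"""The two-tier super-region hierarchy.

Supervoxels start as a regular 3D grid of seeds that is iteratively
deformed toward intensity boundaries (SLIC-style local k-means in a joint
intensity/space metric).  Megavoxels are then formed by greedily merging
adjacent supervoxels with similar intensity histograms on the region
adjacency graph (RAG).  Both tiers are deterministic: there is no random
initialisation and ties are broken toward the lowest region id.

Voxel connectivity is the 6-neighbourhood (face adjacency) at both tiers.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

MAX_SHAPE_PRODUCT = 1024  # supervoxel cell-volume cap

DEFAULT_SV_SHAPE = (10, 10, 10)
DEFAULT_SV_SPACING = (1.0, 1.0, 1.0)
DEFAULT_SV_COMPACTNESS = 20.0
DEFAULT_MV_LAMBDA = 0.1
DEFAULT_MV_NUM_BINS = 20

_SLIC_ITERATIONS = 10
_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SupervoxelPartition:
    """Dense, total, 6-connected partition of the ROI into supervoxels."""

    labels: np.ndarray  # int32 (z, y, x), ids dense in [0, n_regions)
    n_regions: int
    params: dict = field(default_factory=dict)

    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_regions)


@dataclass
class MegavoxelPartition:
    """Second tier: each megavoxel is a connected union of supervoxels."""

    sv_to_mv: np.ndarray  # megavoxel id per supervoxel id
    n_regions: int
    params: dict = field(default_factory=dict)

    def voxel_labels(self, svp: SupervoxelPartition) -> np.ndarray:
        return self.sv_to_mv[svp.labels]


def _grid_of(source) -> np.ndarray:
    data = getattr(source, "data", source)
    return np.asarray(data, dtype=np.float64)


def _rescale01(grid):
    lo, hi = grid.min(), grid.max()
    if hi == lo:
        return np.zeros_like(grid)
    return (grid - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# supervoxels


def compute_supervoxels(source, shape=DEFAULT_SV_SHAPE, spacing=DEFAULT_SV_SPACING,
                        compactness: float = DEFAULT_SV_COMPACTNESS,
                        n_iter: int = _SLIC_ITERATIONS) -> SupervoxelPartition:
    """SLIC-style supervoxels over a feature channel or raw grid.

    ``shape`` (sz, sy, sx) is the seed-grid cell size and the approximate
    supervoxel shape; its product must not exceed 1024.  ``spacing`` weights
    the spatial distance per axis, so a larger weight on an axis makes
    boundaries along that axis more expensive to cross (supervoxels deform
    less along it).  ``compactness`` trades intensity fidelity against
    spatial regularity: lower values let supervoxels deform more.

    The intensity term uses the source rescaled to [0, 1]; the spatial term
    is normalised by the cell size per axis, and compactness is divided by
    100 so that values in the conventional [1, 200] range move the balance
    through the useful regime.  Ten assignment/update iterations are run,
    then connectivity is enforced by merging orphaned fragments into their
    dominant neighbouring supervoxel and relabelling densely.
    """
    grid = _grid_of(source)
    if grid.ndim != 3:
        raise ValueError(f"source must be 3D, got shape {grid.shape}")
    shape = tuple(int(s) for s in np.broadcast_to(shape, (3,)))
    spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
    if any(s < 1 for s in shape):
        raise ValueError(f"shape components must be >= 1, got {shape}")
    if int(np.prod(shape)) > MAX_SHAPE_PRODUCT:
        raise ValueError(
            f"supervoxel shape product {np.prod(shape)} exceeds {MAX_SHAPE_PRODUCT}; "
            f"shape components multiplied together must be {MAX_SHAPE_PRODUCT} or less"
        )
    if any(s > e for s, e in zip(shape, grid.shape)):
        raise ValueError(f"shape {shape} larger than ROI extent {grid.shape} on some axis")
    if compactness <= 0:
        raise ValueError(f"compactness must be > 0, got {compactness}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")

    intens = _rescale01(grid)
    seeds = _initial_seeds(intens, shape)
    centers_pos = seeds.astype(np.float64)  # (K, 3)
    centers_int = intens[tuple(seeds.T)]

    m = compactness / 100.0
    inv_cell = np.array([spacing[a] / shape[a] for a in range(3)])

    zz, yy, xx = np.meshgrid(*[np.arange(e) for e in grid.shape], indexing="ij")
    coords = (zz, yy, xx)

    labels = np.zeros(grid.shape, dtype=np.int32)
    for _ in range(n_iter):
        dist = np.full(grid.shape, np.inf)
        labels.fill(-1)
        for k in range(len(centers_pos)):
            window = tuple(
                slice(max(0, int(np.floor(centers_pos[k, a])) - shape[a]),
                      min(grid.shape[a], int(np.ceil(centers_pos[k, a])) + shape[a] + 1))
                for a in range(3)
            )
            d2 = (intens[window] - centers_int[k]) ** 2
            for a in range(3):
                d2 = d2 + (m * (coords[a][window] - centers_pos[k, a]) * inv_cell[a]) ** 2
            better = d2 < dist[window]  # strict: ties keep the lower id
            dist[window][better] = d2[better]
            labels[window][better] = k
        # update centers (empty clusters keep their previous center)
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=len(centers_pos)).astype(np.float64)
        nz = counts > 0
        for a, c in enumerate(coords):
            s = np.bincount(flat, weights=c.ravel(), minlength=len(centers_pos))
            centers_pos[nz, a] = s[nz] / counts[nz]
        si = np.bincount(flat, weights=intens.ravel(), minlength=len(centers_pos))
        centers_int[nz] = si[nz] / counts[nz]

    labels = _enforce_connectivity(labels, int(np.prod(shape)))
    n_regions = int(labels.max()) + 1
    return SupervoxelPartition(
        labels=labels, n_regions=n_regions,
        params={"source": getattr(source, "name", "__data__"), "shape": list(shape),
                "spacing": list(spacing), "compactness": compactness},
    )


def _initial_seeds(intens, shape):
    """Regular grid of cell centers, each nudged to the lowest-gradient
    voxel of its 3x3x3 neighbourhood to keep seeds off boundaries."""
    axes = []
    for a in range(3):
        n = max(1, int(round(intens.shape[a] / shape[a])))
        # centers of n equal cells along the axis
        edges = np.linspace(0, intens.shape[a], n + 1)
        axes.append(np.clip(((edges[:-1] + edges[1:]) / 2).astype(int), 0,
                            intens.shape[a] - 1))
    gz, gy, gx = np.gradient(intens)
    gmag = gz ** 2 + gy ** 2 + gx ** 2
    seeds = []
    for z in axes[0]:
        for y in axes[1]:
            for x in axes[2]:
                window = tuple(slice(max(0, c - 1), min(e, c + 2))
                               for c, e in zip((z, y, x), intens.shape))
                local = gmag[window]
                off = np.unravel_index(int(np.argmin(local)), local.shape)
                seeds.append([window[a].start + off[a] for a in range(3)])
    return np.asarray(seeds, dtype=np.int64)


def _enforce_connectivity(labels, cell_volume):
    """Split disconnected supervoxels and absorb orphan fragments.

    For every id, the largest 6-connected component keeps the id; smaller
    fragments are merged into the most common adjacent kept label (lowest id
    on ties).  Output ids are dense in [0, n).
    """
    final = np.full(labels.shape, -1, dtype=np.int32)
    orphans = []
    for lab in np.unique(labels):
        comp, ncomp = ndimage.label(labels == lab, structure=_STRUCTURE_6)
        if ncomp == 0:
            continue
        if lab < 0:  # voxels no window reached: all fragments are orphans
            for c in range(1, ncomp + 1):
                orphans.append(comp == c)
            continue
        sizes = np.bincount(comp.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        final[comp == keep] = lab
        for c in range(1, ncomp + 1):
            if c != keep:
                orphans.append(comp == c)
    # iteratively absorb orphan fragments into an adjacent assigned region
    while orphans:
        progress = False
        remaining = []
        for mask in orphans:
            border = ndimage.binary_dilation(mask, structure=_STRUCTURE_6) & ~mask
            neigh = final[border]
            neigh = neigh[neigh >= 0]
            if neigh.size:
                counts = np.bincount(neigh)
                final[mask] = int(np.argmax(counts))  # argmax -> lowest id on ties
                progress = True
            else:
                remaining.append(mask)
        orphans = remaining
        if not progress and orphans:  # pathological: everything orphaned
            final[orphans.pop(0)] = int(final.max()) + 1
    # dense relabel
    uniq, dense = np.unique(final, return_inverse=True)
    return dense.reshape(final.shape).astype(np.int32)


# ---------------------------------------------------------------------------
# adjacency and per-region reductions


def adjacency_edges(labels) -> np.ndarray:
    """Unique (i, j) pairs (i < j) of 6-adjacent region ids."""
    pairs = []
    for ax in range(3):
        a = labels.swapaxes(0, ax)[:-1].swapaxes(0, ax).ravel()
        b = labels.swapaxes(0, ax)[1:].swapaxes(0, ax).ravel()
        diff = a != b
        pairs.append(np.stack([a[diff], b[diff]], axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    e = np.concatenate(pairs).astype(np.int64)
    e.sort(axis=1)
    return np.unique(e, axis=0)


def region_means(partition, channel) -> np.ndarray:
    """Mean of a channel over each region of a partition."""
    grid = _grid_of(channel)
    labels = partition.labels if hasattr(partition, "labels") else np.asarray(partition)
    if grid.shape != labels.shape:
        raise ValueError(f"channel shape {grid.shape} != partition shape {labels.shape}")
    n = int(labels.max()) + 1
    sums = np.bincount(labels.ravel(), weights=grid.ravel(), minlength=n)
    counts = np.bincount(labels.ravel(), minlength=n)
    return sums / counts


def boundary_map(partition) -> np.ndarray:
    """Binary grid marking voxels with a 6-neighbour of a different region."""
    labels = partition.labels if hasattr(partition, "labels") else np.asarray(partition)
    out = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        diff = labels[tuple(sl_a)] != labels[tuple(sl_b)]
        out[tuple(sl_a)] |= diff
        out[tuple(sl_b)] |= diff
    return out


# ---------------------------------------------------------------------------
# megavoxels


def _chi2(h1, h2):
    denom = h1 + h2
    num = (h1 - h2) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / denom, 0.0)
    return 0.5 * float(terms.sum())


def compute_megavoxels(source, svp: SupervoxelPartition,
                       lambda_mv: float = DEFAULT_MV_LAMBDA,
                       num_bins: int = DEFAULT_MV_NUM_BINS,
                       gamma=None) -> MegavoxelPartition:
    """Merge similar adjacent supervoxels into megavoxels.

    Each supervoxel gets a ``num_bins``-bin normalised intensity histogram
    of the source channel (rescaled to [0, 1]).  Greedy hierarchical
    agglomeration then repeatedly merges the RAG edge with the smallest
    chi-squared histogram dissimilarity, recomputing the merged region's
    histogram (voxel-count weighted), until the cheapest edge exceeds
    ``lambda_mv``.  Because the merge sequence does not depend on
    ``lambda_mv`` (the threshold only truncates it), the megavoxel count is
    non-increasing in ``lambda_mv`` by construction.

    ``gamma`` (None | "auto" | (0, 1]) applies the similarity-sharpening
    map w -> w**(1/gamma) to the edge dissimilarities (all in [0, 1]):
    small gamma drives dissimilarities toward 0, merging more pairs and
    yielding fewer megavoxels; gamma = 1 is the identity; "auto" uses the
    median initial edge dissimilarity.  Ties break toward the lowest pair
    of region ids, making the result deterministic.
    """
    if svp is None:
        raise ValueError("compute_megavoxels requires a supervoxel partition")
    if not (0 < lambda_mv <= 1):
        raise ValueError(f"lambda_mv must be in (0, 1], got {lambda_mv}")
    if lambda_mv < 0.01:
        warnings.warn(f"lambda_mv={lambda_mv} is below the recommended range [0.01, 1]")
    if num_bins < 2:
        raise ValueError(f"num_bins must be >= 2, got {num_bins}")
    if gamma is not None and gamma != "auto":
        gamma = float(gamma)
        if not (0 < gamma <= 1):
            raise ValueError(f"gamma must be None, 'auto' or in (0, 1], got {gamma}")

    grid = _rescale01(_grid_of(source))
    if grid.shape != svp.labels.shape:
        raise ValueError("source shape does not match supervoxel partition")
    n = svp.n_regions

    # per-supervoxel histograms (counts, normalised later on demand)
    bin_idx = np.minimum((grid * num_bins).astype(np.int64), num_bins - 1)
    flat = svp.labels.ravel() * num_bins + bin_idx.ravel()
    hist = np.bincount(flat, minlength=n * num_bins).astype(np.float64)
    hist = hist.reshape(n, num_bins)
    counts = hist.sum(axis=1)

    edges = adjacency_edges(svp.labels)
    neighbors = [set() for _ in range(n)]
    for i, j in edges:
        neighbors[i].add(int(j))
        neighbors[j].add(int(i))

    def norm(h):
        s = h.sum()
        return h / s if s > 0 else h

    if gamma == "auto":
        init = [_chi2(norm(hist[i]), norm(hist[j])) for i, j in edges]
        gamma = float(np.median(init)) if init else None
        if gamma is not None and gamma <= 0:
            gamma = None  # all edges identical: sharpening is a no-op anyway

    def weight(i, j):
        w = _chi2(norm(hist[i]), norm(hist[j]))
        if gamma is not None:
            w = w ** (1.0 / gamma)
        return w

    # union-find over supervoxel ids; heap with lazy invalidation
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return int(i)

    heap = [(weight(int(i), int(j)), int(i), int(j)) for i, j in edges]
    heapq.heapify(heap)

    # lazy heap: entries may be stale after a merge; on pop, canonicalise the
    # endpoints and recompute the weight, re-queueing if anything changed, so
    # the break below only ever fires on a currently-valid cheapest edge.
    while heap:
        w, i, j = heapq.heappop(heap)
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        a, b = min(ri, rj), max(ri, rj)
        wt = weight(a, b)
        if (w, i, j) != (wt, a, b):
            heapq.heappush(heap, (wt, a, b))
            continue
        if wt > lambda_mv:
            break
        # merge the larger id into the smaller (lowest-id tie rule)
        parent[b] = a
        hist[a] += hist[b]
        counts[a] += counts[b]
        neighbors[a].discard(b)
        neighbors[b].discard(a)
        for nb in list(neighbors[b]):
            neighbors[nb].discard(b)
            rnb = find(nb)
            if rnb != a:
                neighbors[a].add(rnb)
                neighbors[rnb].add(a)
                heapq.heappush(heap, (weight(a, rnb), min(a, rnb), max(a, rnb)))
        neighbors[b] = set()

    roots = np.array([find(i) for i in range(n)])
    uniq, dense = np.unique(roots, return_inverse=True)
    sv_to_mv = dense.astype(np.int32)
    return MegavoxelPartition(
        sv_to_mv=sv_to_mv, n_regions=len(uniq),
        params={"source": getattr(source, "name", "__data__"), "lambda_mv": lambda_mv,
                "num_bins": num_bins,
                "gamma": gamma if gamma is None else float(gamma)},
    )
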