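"""Supervoxel/megavoxel hierarchy: partition contracts, boundary adherence,
merging semantics and determinism, checked against brute-force oracles and
(for boundary recall) against an independent SLIC implementation."""

import numpy as np
import pytest
from scipy import ndimage

from srseg import feature_channels as fc
from srseg import metrics, phantoms
from srseg import super_regions as sr


def assert_valid_partition(labels, n_regions):
    """Total assignment, dense ids, 6-connected regions."""
    assert labels.min() == 0
    assert labels.max() == n_regions - 1
    assert np.array_equal(np.unique(labels), np.arange(n_regions))
    structure = ndimage.generate_binary_structure(3, 1)
    for lab in range(n_regions):
        assert ndimage.label(labels == lab, structure)[1] == 1, \
            f"region {lab} is disconnected"


# ---------------------------------------------------------------------------
# supervoxels


class TestSupervoxels:
    def test_uniform_grid_gives_regular_blocks(self):
        svp = sr.compute_supervoxels(np.zeros((20, 20, 20)), shape=(10, 10, 10),
                                     compactness=20)
        assert svp.n_regions == 8
        sizes = svp.region_sizes()
        np.testing.assert_array_equal(sizes, np.full(8, 1000))
        # each region is a 10^3 cube (near-cuboidal in the zero-gradient limit)
        for lab in range(8):
            box = ndimage.find_objects((svp.labels == lab).astype(np.int8))[0]
            assert all(s.stop - s.start == 10 for s in box)

    def test_shape_product_cap(self):
        with pytest.raises(ValueError, match="1024"):
            sr.compute_supervoxels(np.zeros((32, 32, 32)), shape=(16, 16, 8))
        # product exactly 1024 is allowed
        svp = sr.compute_supervoxels(np.zeros((32, 32, 32)), shape=(16, 8, 8))
        assert svp.n_regions > 0

    def test_shape_larger_than_roi_rejected(self):
        with pytest.raises(ValueError, match="larger than ROI"):
            sr.compute_supervoxels(np.zeros((8, 8, 8)), shape=(10, 10, 10))

    def test_boundary_recall_on_two_phase_phantom(self):
        ph = phantoms.make_two_phase(size=48, seed=2)
        tv = fc.total_variation(ph.volume, lambda_tv=10, n_iter=100)
        svp = sr.compute_supervoxels(tv, shape=(10, 10, 10), compactness=20)
        recall = metrics.boundary_recall(svp.labels, ph.truth, tolerance=1)
        assert recall >= 0.95
        # independent SLIC implementation reaches a comparable recall,
        # confirming the phantom/parameters make the task well posed
        from skimage.segmentation import slic

        ref = slic(tv.data.astype(float), n_segments=125, compactness=0.02,
                   channel_axis=None, start_label=0)
        ref_recall = metrics.boundary_recall(ref, ph.truth, tolerance=1)
        assert ref_recall >= 0.95

    def test_undersegmentation_error_below_5_percent(self):
        ph = phantoms.make_two_phase(size=48, seed=5)
        tv = fc.total_variation(ph.volume, lambda_tv=10, n_iter=100)
        svp = sr.compute_supervoxels(tv, shape=(10, 10, 10), compactness=20)
        assert metrics.undersegmentation_error(svp.labels, ph.truth) < 0.05

    def test_partition_invariants_on_noisy_phantom(self):
        ph = phantoms.make_multiregion(size=32, seed=4)
        svp = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=30)
        assert_valid_partition(svp.labels, svp.n_regions)

    def test_determinism(self):
        ph = phantoms.make_two_phase(size=32, seed=9)
        a = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=20)
        b = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=20)
        np.testing.assert_array_equal(a.labels, b.labels)


# ---------------------------------------------------------------------------
# megavoxel brute-force oracle


def brute_force_megavoxels(grid, svp, lambda_mv, num_bins, gamma=None):
    """O(n^3) re-derivation: recompute all pairwise dissimilarities from
    scratch each step, merge the globally cheapest adjacent pair."""
    lo, hi = grid.min(), grid.max()
    scaled = np.zeros_like(grid, dtype=float) if hi == lo else (grid - lo) / (hi - lo)
    bins = np.minimum((scaled * num_bins).astype(int), num_bins - 1)
    members = {i: {i} for i in range(svp.n_regions)}
    edges = {tuple(e) for e in sr.adjacency_edges(svp.labels)}

    def hist_of(group):
        sel = np.isin(svp.labels, list(group))
        h = np.bincount(bins[sel], minlength=num_bins).astype(float)
        return h / h.sum()

    def dissim(ga, gb):
        ha, hb = hist_of(ga), hist_of(gb)
        denom = ha + hb
        with np.errstate(invalid="ignore", divide="ignore"):
            w = 0.5 * np.sum(np.where(denom > 0, (ha - hb) ** 2 / denom, 0.0))
        if gamma is not None:
            w = w ** (1.0 / gamma)
        return w

    def adjacent(ga, gb):
        return any((min(i, j), max(i, j)) in edges for i in ga for j in gb)

    while True:
        keys = sorted(members)
        best = None
        for ii, a in enumerate(keys):
            for b in keys[ii + 1:]:
                if adjacent(members[a], members[b]):
                    w = dissim(members[a], members[b])
                    if best is None or (w, a, b) < best:
                        best = (w, a, b)
        if best is None or best[0] > lambda_mv:
            break
        _, a, b = best
        members[a] |= members.pop(b)
    sv_to_mv = np.empty(svp.n_regions, dtype=int)
    for new_id, key in enumerate(sorted(members)):
        for svid in members[key]:
            sv_to_mv[svid] = new_id
    return sv_to_mv


class TestMegavoxels:
    def test_two_phases_merge_to_exactly_two(self):
        ph = phantoms.make_two_phase(size=24, noise_sd=0, seed=0)
        svp = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=20)
        mvp = sr.compute_megavoxels(ph.volume, svp, lambda_mv=0.1, num_bins=20)
        assert mvp.n_regions == 2
        # megavoxels coincide with the phases
        vox = mvp.voxel_labels(svp)
        assert len(np.unique(vox[ph.truth == 0])) == 1
        assert len(np.unique(vox[ph.truth == 1])) == 1

    @pytest.mark.parametrize("gamma", [None, 0.5])
    def test_matches_brute_force_merge_oracle(self, gamma):
        ph = phantoms.make_two_phase(size=18, noise_sd=30, seed=7)
        svp = sr.compute_supervoxels(ph.volume, shape=(6, 6, 6), compactness=20)
        assert svp.n_regions <= 30
        mvp = sr.compute_megavoxels(ph.volume, svp, lambda_mv=0.3, num_bins=10,
                                    gamma=gamma)
        expected = brute_force_megavoxels(ph.volume, svp, 0.3, 10, gamma=gamma)
        np.testing.assert_array_equal(mvp.sv_to_mv, expected)

    def test_count_non_increasing_in_lambda(self):
        ph = phantoms.make_multiregion(size=32, seed=11)
        svp = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=30)
        counts = [sr.compute_megavoxels(ph.volume, svp, lambda_mv=lam,
                                        num_bins=20).n_regions
                  for lam in (0.05, 0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_small_gamma_gives_fewer_or_equal_megavoxels(self):
        ph = phantoms.make_multiregion(size=32, seed=12)
        svp = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=30)
        n_none = sr.compute_megavoxels(ph.volume, svp, lambda_mv=0.2,
                                       num_bins=20, gamma=None).n_regions
        n_small = sr.compute_megavoxels(ph.volume, svp, lambda_mv=0.2,
                                        num_bins=20, gamma=0.2).n_regions
        assert n_small <= n_none

    def test_hierarchy_and_connectivity(self):
        ph = phantoms.make_multiregion(size=32, seed=13)
        svp = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=30)
        mvp = sr.compute_megavoxels(ph.volume, svp, lambda_mv=0.2, num_bins=20)
        # total map over supervoxels; counts ordered voxels >= sv >= mv
        assert len(mvp.sv_to_mv) == svp.n_regions
        assert mvp.n_regions <= svp.n_regions <= svp.labels.size
        assert_valid_partition(mvp.voxel_labels(svp), mvp.n_regions)

    def test_parameter_validation(self):
        ph = phantoms.make_two_phase(size=16, seed=0)
        svp = sr.compute_supervoxels(ph.volume, shape=(8, 8, 8), compactness=20)
        for bad in (dict(lambda_mv=0), dict(lambda_mv=1.5), dict(num_bins=1),
                    dict(gamma=2.0)):
            with pytest.raises(ValueError):
                sr.compute_megavoxels(ph.volume, svp, **{**dict(lambda_mv=0.1,
                                                                num_bins=10), **bad})
        with pytest.raises(ValueError):
            sr.compute_megavoxels(ph.volume, None, lambda_mv=0.1, num_bins=10)


# ---------------------------------------------------------------------------
# per-region reductions


class TestRegionOps:
    def test_region_means_constant(self):
        svp = sr.compute_supervoxels(np.zeros((16, 16, 16)), shape=(8, 8, 8))
        means = sr.region_means(svp, np.full((16, 16, 16), 4.2))
        np.testing.assert_allclose(means, 4.2)

    def test_region_means_counting_oracle(self, rng):
        grid = rng.normal(size=(16, 16, 16))
        svp = sr.compute_supervoxels(grid, shape=(8, 8, 8), compactness=20)
        means = sr.region_means(svp, grid)
        for lab in range(svp.n_regions):
            np.testing.assert_allclose(means[lab], grid[svp.labels == lab].mean())

    def test_boundary_map_single_region_empty(self):
        assert sr.boundary_map(np.zeros((8, 8, 8), dtype=int)).sum() == 0

    def test_boundary_map_regular_blocks_marks_midplanes(self):
        svp = sr.compute_supervoxels(np.zeros((20, 20, 20)), shape=(10, 10, 10))
        bmap = sr.boundary_map(svp)
        expected = np.zeros((20, 20, 20), dtype=bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            sl[ax] = slice(9, 11)  # both faces of each mid-plane cut
            expected[tuple(sl)] = True
        np.testing.assert_array_equal(bmap, expected)

    def test_boundary_map_matches_neighbor_scan(self, rng):
        labels = rng.integers(0, 4, size=(10, 10, 10))
        bmap = sr.boundary_map(labels)
        expected = np.zeros_like(bmap)
        for z in range(10):
            for y in range(10):
                for x in range(10):
                    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        nz, ny, nx = z + dz, y + dy, x + dx
                        if 0 <= nz < 10 and 0 <= ny < 10 and 0 <= nx < 10 \
                                and labels[nz, ny, nx] != labels[z, y, x]:
                            expected[z, y, x] = True
        np.testing.assert_array_equal(bmap, expected)
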