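"""Feature-channel operators against dense brute-force oracles.

Every operator is checked on small grids against an independent dense-math
implementation (direct convolution with the sampled kernel, explicit
per-voxel tensor determinants, loop-based TV iterations, counting), plus
the algebraic properties the operators must satisfy (constants map to
constants, linearity, clamping, TV decrease).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from srseg import feature_channels as fc
from srseg import volume_io as vio


# ---------------------------------------------------------------------------
# oracles


def gaussian_kernel_1d(sigma, truncate=4.0):
    """Sampled, normalised Gaussian — the kernel scipy uses."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def dense_convolve_reflect(grid, kernel3d):
    """Direct dense 3D convolution with reflect (symmetric) padding."""
    rz, ry, rx = (s // 2 for s in kernel3d.shape)
    padded = np.pad(grid, ((rz, rz), (ry, ry), (rx, rx)), mode="symmetric")
    out = np.zeros_like(grid, dtype=np.float64)
    kz, ky, kx = kernel3d.shape
    for dz in range(kz):
        for dy in range(ky):
            for dx in range(kx):
                out += kernel3d[dz, dy, dx] * padded[
                    dz:dz + grid.shape[0], dy:dy + grid.shape[1], dx:dx + grid.shape[2]]
    return out


def dense_gaussian(grid, sigma):
    k1 = gaussian_kernel_1d(sigma)
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    return dense_convolve_reflect(grid, kernel)


def impulse_response_1d(filter_1d_func, radius):
    """Extract a 1D filter's kernel from its response to a unit impulse."""
    imp = np.zeros(4 * radius + 1)
    imp[2 * radius] = 1.0
    resp = filter_1d_func(imp)
    return resp[radius:3 * radius + 1][::-1]


def tv_chambolle_loops(image, weight, n_iter):
    """Loop-based re-derivation of the dual projection TV scheme."""
    ndim = image.ndim
    shape = image.shape
    p = np.zeros((ndim,) + shape)
    tau = 1.0 / (2.0 * ndim)
    out = image.copy()
    for it in range(n_iter + 1):
        if it > 0:
            div = np.zeros(shape)
            for z in range(shape[0]):
                for y in range(shape[1]):
                    for x in range(shape[2]):
                        v = -p[0, z, y, x] - p[1, z, y, x] - p[2, z, y, x]
                        if z > 0:
                            v += p[0, z - 1, y, x]
                        if y > 0:
                            v += p[1, z, y - 1, x]
                        if x > 0:
                            v += p[2, z, y, x - 1]
                        div[z, y, x] = v
            out = image + div
        if it == n_iter:
            break
        g = np.zeros((ndim,) + shape)
        g[0, :-1] = np.diff(out, axis=0)
        g[1, :, :-1] = np.diff(out, axis=1)
        g[2, :, :, :-1] = np.diff(out, axis=2)
        norm = np.sqrt((g ** 2).sum(axis=0))
        p = (p - tau * g) / (1.0 + norm * tau / weight)
    return out


# ---------------------------------------------------------------------------
# constant-grid behaviour for every operator


@pytest.mark.parametrize("op,expect,atol", [
    (lambda g: fc.gaussian(g, sigma=2).data, "same", 1e-9),
    (lambda g: fc.total_variation(g, lambda_tv=5, n_iter=20).data, "same", 1e-9),
    (lambda g: fc.threshold(g, vmin=0).data, "ones", 1e-9),
    (lambda g: fc.gaussian_centering(g, sigma=2).data, "zeros", 1e-9),
    (lambda g: fc.gaussian_normalization(g, sigma=2).data, "zeros", 1e-9),
    # the sampled truncated 2nd-derivative kernel has a small nonzero sum,
    # so the discrete LoG of a constant carries a ~1e-4-relative DC residual
    (lambda g: fc.laplacian_of_gaussian(g, sigma_log=2).data, "zeros", 5e-3),
    (lambda g: fc.difference_of_gaussians(g, sigma_init=2).data, "zeros", 1e-9),
    (lambda g: fc.structure_tensor_det(g, sigma1=2, sigma_area=2).data, "zeros", 1e-9),
])
def test_operators_on_constant_grid(op, expect, atol):
    grid = np.full((10, 10, 10), 3.7)
    out = op(grid)
    target = {"same": grid, "ones": np.ones_like(grid),
              "zeros": np.zeros_like(grid)}[expect]
    np.testing.assert_allclose(out, target, atol=atol)


# ---------------------------------------------------------------------------
# gaussian


def test_gaussian_impulse_matches_dense_convolution():
    grid = np.zeros((11, 11, 11))
    grid[5, 5, 5] = 1.0
    out = fc.gaussian(grid, sigma=1).data
    np.testing.assert_allclose(out, dense_gaussian(grid, 1.0), rtol=1e-6, atol=1e-12)


def test_gaussian_on_random_grid_matches_dense_oracle(small_grid):
    out = fc.gaussian(small_grid, sigma=1.5).data
    expected = dense_gaussian(small_grid, 1.5)
    np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-10)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(hnp.arrays(np.float64, (6, 6, 6),
                  elements=st.floats(-10, 10, allow_nan=False)),
       hnp.arrays(np.float64, (6, 6, 6),
                  elements=st.floats(-10, 10, allow_nan=False)),
       st.floats(-3, 3), st.floats(-3, 3))
def test_gaussian_is_linear(gi, gj, a, b):
    lhs = fc.gaussian(a * gi + b * gj, sigma=1).data
    rhs = a * fc.gaussian(gi, sigma=1).data + b * fc.gaussian(gj, sigma=1).data
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_gaussian_default_sigma_is_one():
    assert fc.DEFAULT_SIGMA_GAUSSIAN == 1.0


def test_gaussian_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        fc.gaussian(np.zeros((4, 4, 4)), sigma=0)


# ---------------------------------------------------------------------------
# total variation


def test_tv_reduces_discrete_total_variation(rng):
    step = np.zeros((12, 12, 12))
    step[:, :, 6:] = 1.0
    noisy = step + rng.normal(0, 0.2, step.shape)
    out = fc.total_variation(noisy, lambda_tv=0.5, n_iter=50).data
    assert (fc.discrete_total_variation(out)
            < fc.discrete_total_variation(noisy))


def test_tv_matches_loop_oracle(rng):
    grid = rng.normal(size=(8, 8, 8))
    out = fc.total_variation(grid, lambda_tv=1.0, n_iter=15).data
    expected = tv_chambolle_loops(grid, weight=1.0, n_iter=15)
    np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-10)


def test_tv_clamp_bounds_applied_before_denoising():
    grid = np.linspace(-5, 5, 6 ** 3).reshape(6, 6, 6)
    out = fc.total_variation(grid, lambda_tv=0.01, n_iter=1, clamp=(1, None)).data
    # weight ~ 0 leaves the clamped image nearly untouched
    assert out.min() >= 1 - 1e-6

    clamped = fc.total_variation(grid, lambda_tv=5, n_iter=30, clamp=(-2, 2)).data
    assert clamped.min() >= -2 - 1e-9 and clamped.max() <= 2 + 1e-9


def test_tv_defaults_and_validation():
    assert fc.DEFAULT_LAMBDA_TV == 10.0
    assert fc.DEFAULT_N_ITER_TV == 100
    with pytest.raises(ValueError):
        fc.total_variation(np.zeros((4, 4, 4)), clamp=(3, 1))
    with pytest.raises(ValueError):
        fc.total_variation(np.zeros((4, 4, 4)), n_iter=0)


# ---------------------------------------------------------------------------
# threshold


def test_threshold_explicit_examples():
    grid = np.where(np.indices((4, 4, 4)).sum(0) % 2 == 0, -1.0, 2.0)
    out = fc.threshold(grid, vmin=0).data
    np.testing.assert_array_equal(out == 1, grid == 2)
    assert fc.threshold(np.full((4, 4, 4), -3.0), vmin=0).data.sum() == 0
    with pytest.raises(ValueError):
        fc.threshold(grid)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(hnp.arrays(np.float64, (5, 5, 5), elements=st.floats(-5, 5)),
       st.floats(-4, 4), st.floats(0, 4))
def test_threshold_count_matches_brute_force(grid, vmin, width):
    vmax = vmin + width
    out = fc.threshold(grid, vmin=vmin, vmax=vmax).data
    expected = sum(1 for v in grid.ravel() if vmin <= v <= vmax)
    assert out.sum() == expected


# ---------------------------------------------------------------------------
# centering / normalization


def test_centering_matches_formula(small_grid):
    out = fc.gaussian_centering(small_grid, sigma=2).data
    np.testing.assert_allclose(out, small_grid - dense_gaussian(small_grid, 2),
                               rtol=1e-6, atol=1e-10)


def test_centering_zero_mean_under_periodic_boundary(rng):
    grid = rng.normal(size=(16, 16, 16)) * 100
    out = fc.gaussian_centering(grid, sigma=2, boundary="wrap").data
    assert abs(out.mean()) < 1e-6 * (grid.max() - grid.min())


def test_normalization_matches_formula(small_grid):
    sigma = 2.0
    out = fc.gaussian_normalization(small_grid, sigma=sigma).data
    centered = small_grid - dense_gaussian(small_grid, sigma)
    eps = 1e-8 * small_grid.var()
    expected = centered / np.sqrt(dense_gaussian(centered ** 2, sigma) + eps)
    np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-10)


def test_normalization_affine_invariant(small_grid):
    base = fc.gaussian_normalization(small_grid, sigma=2).data
    scaled = fc.gaussian_normalization(3.5 * small_grid + 11.0, sigma=2).data
    np.testing.assert_allclose(scaled, base, rtol=1e-5, atol=1e-7)


def test_centering_normalization_default_sigma_is_two():
    assert fc.DEFAULT_SIGMA_CENTERING == 2.0
    assert fc.DEFAULT_SIGMA_NORMALIZATION == 2.0


# ---------------------------------------------------------------------------
# LoG / DoG


def test_log_bright_blob_peaks_at_center():
    grid = np.zeros((15, 15, 15))
    zz, yy, xx = np.mgrid[:15, :15, :15]
    grid += np.exp(-((zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2) / (2 * 2.0 ** 2))
    out = fc.laplacian_of_gaussian(grid, sigma_log=2, response="bright").data
    assert np.unravel_index(np.argmax(out), out.shape) == (7, 7, 7)
    # dark response is the negation
    dark = fc.laplacian_of_gaussian(grid, sigma_log=2, response="dark").data
    np.testing.assert_allclose(dark, -out, atol=1e-12)


def test_log_matches_axiswise_second_derivative_oracle(small_grid):
    from scipy.ndimage import gaussian_filter1d

    sigma = 1.5
    radius = int(4.0 * sigma + 0.5)
    k0 = impulse_response_1d(lambda a: gaussian_filter1d(a, sigma, mode="constant"),
                             radius)
    k2 = impulse_response_1d(
        lambda a: gaussian_filter1d(a, sigma, order=2, mode="constant"), radius)

    def kernel3d(order_axis):
        ks = [k2 if ax == order_axis else k0 for ax in range(3)]
        return ks[0][:, None, None] * ks[1][None, :, None] * ks[2][None, None, :]

    expected = -sum(dense_convolve_reflect(small_grid, kernel3d(ax))
                    for ax in range(3))
    out = fc.laplacian_of_gaussian(small_grid, sigma_log=sigma,
                                   response="bright").data
    np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-9)


def test_log_thresh_flag_zeroes_negative_responses(small_grid):
    out = fc.laplacian_of_gaussian(small_grid, sigma_log=1, thresh_flag=True).data
    assert out.min() >= 0


def test_log_defaults():
    assert fc.DEFAULT_SIGMA_LOG == 2.0


def test_dog_equals_difference_of_gaussian_channels(small_grid):
    out = fc.difference_of_gaussians(small_grid, sigma_init=2, sigma_ratio=1.6).data
    g1 = fc.gaussian(small_grid, sigma=2).data
    g2 = fc.gaussian(small_grid, sigma=2 * 1.6).data
    np.testing.assert_allclose(out, g1 - g2, atol=1e-12)


def test_dog_default_ratio():
    assert fc.DEFAULT_SIGMA_RATIO_DOG == 1.6


# ---------------------------------------------------------------------------
# structure tensor


def test_structure_tensor_det_matches_per_voxel_determinant(small_grid):
    from scipy.ndimage import gaussian_filter

    sigma1, sigma_area = 1.5, 2.0
    grads = [gaussian_filter(small_grid, sigma1, order=[int(ax == a) for a in range(3)],
                             mode="reflect", truncate=4.0) for ax in range(3)]
    # assemble the full 3x3 tensor per voxel; determinant via LAPACK
    T = np.zeros(small_grid.shape + (3, 3))
    for i in range(3):
        for j in range(3):
            T[..., i, j] = gaussian_filter(grads[i] * grads[j], sigma_area,
                                           mode="reflect", truncate=4.0)
    expected = np.linalg.det(T)
    out = fc.structure_tensor_det(small_grid, sigma1=sigma1, sigma_area=sigma_area).data
    np.testing.assert_allclose(out, expected, rtol=1e-6, atol=1e-10)
    assert out.min() > -1e-8 * max(1.0, np.abs(out).max())


def test_structure_tensor_defaults():
    assert fc.DEFAULT_SIGMA1_ST == 2.0
    assert fc.DEFAULT_SIGMA_AREA_ST == 2.0


# ---------------------------------------------------------------------------
# queue


def _ws(grid):
    return vio.Workspace(volume=vio.Volume(grid))


def test_queue_chain_equals_manual_composition(rng):
    grid = rng.normal(size=(10, 10, 10))
    ws = _ws(grid)
    fc.compute_queue(ws, [
        {"name": "g", "operator": "gaussian", "params": {"sigma": 1}},
        {"name": "tv", "operator": "total_variation", "source": "g",
         "params": {"lambda_tv": 2, "n_iter": 20}},
    ])
    manual = fc.total_variation(fc.gaussian(grid, sigma=1).data,
                                lambda_tv=2, n_iter=20).data
    np.testing.assert_allclose(ws.channels["tv"].data, manual, atol=1e-12)


def test_queue_resolves_out_of_order_dependencies(rng):
    ws = _ws(rng.normal(size=(8, 8, 8)))
    fc.compute_queue(ws, [
        {"name": "late", "operator": "gaussian", "source": "early",
         "params": {"sigma": 1}},
        {"name": "early", "operator": "gaussian", "params": {"sigma": 1}},
    ])
    assert set(ws.channels) == {"early", "late"}


def test_queue_empty_is_noop(rng):
    ws = _ws(rng.normal(size=(6, 6, 6)))
    fc.compute_queue(ws, [])
    assert not ws.channels


def test_queue_missing_source_and_cycle_rejected(rng):
    ws = _ws(rng.normal(size=(6, 6, 6)))
    with pytest.raises(ValueError, match="undefined source"):
        fc.compute_queue(ws, [{"name": "a", "operator": "gaussian",
                               "source": "ghost", "params": {"sigma": 1}}])
    with pytest.raises(ValueError, match="cyclic"):
        fc.compute_queue(ws, [
            {"name": "a", "operator": "gaussian", "source": "b", "params": {"sigma": 1}},
            {"name": "b", "operator": "gaussian", "source": "a", "params": {"sigma": 1}},
        ])


def test_queue_recompute_invalidates_dependents(rng):
    ws = _ws(rng.normal(size=(6, 6, 6)))
    fc.compute_queue(ws, [
        {"name": "a", "operator": "gaussian", "params": {"sigma": 1}},
        {"name": "b", "operator": "gaussian", "source": "a", "params": {"sigma": 1}},
    ])
    fc.compute_queue(ws, [{"name": "a", "operator": "gaussian",
                           "params": {"sigma": 2}}])
    assert "b" not in ws.channels


def test_out_of_range_parameter_warns(rng):
    with pytest.warns(UserWarning, match="outside the recommended range"):
        fc.gaussian(rng.normal(size=(6, 6, 6)), sigma=50)
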