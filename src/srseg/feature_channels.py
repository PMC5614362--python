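"""Feature channels: derived 3D scalar grids used as sources for
super-regions and classifier descriptors.

Eight operators are provided: Gaussian smoothing, total-variation
denoising, thresholding, Gaussian centering (local mean removal), Gaussian
normalization (local z-score), Laplacian of Gaussian, difference of
Gaussians, and the determinant of the 3D structure tensor.  Each returns a
:class:`FeatureChannel` whose grid matches the ROI extent.  Channels can be
chained (a channel may consume another channel) through
:func:`compute_queue`, which resolves the dependency DAG.

Boundary handling is reflect padding throughout, and Gaussian kernels are
truncated at 4 standard deviations.

Parameter defaults and recommended ranges follow established practice for
tomographic data; values outside the recommended range are accepted with a
warning rather than rejected, since unusual data sometimes needs unusual
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

_TRUNCATE = 4.0  # Gaussian kernel support in standard deviations

#: recommended (lo, hi, default) per parameter, used for range warnings
PARAM_RANGES = {
    "sigma": (0.5, 10.0, None),
    "lambda_tv": (0.1, 30.0, 10.0),
    "spacing_tv": (0.1, 10.0, 1.0),
    "n_iter": (50, 500, 100),
    "sigma_log": (0.5, 10.0, 2.0),
    "sigma_init": (0.5, 10.0, 2.0),
    "sigma_ratio": (1.1, 3.0, 1.6),
    "sigma1": (0.5, 10.0, 2.0),
    "sigma_area": (0.5, 10.0, 2.0),
}

DEFAULT_SIGMA_GAUSSIAN = 1.0
DEFAULT_SIGMA_CENTERING = 2.0
DEFAULT_SIGMA_NORMALIZATION = 2.0
DEFAULT_LAMBDA_TV = 10.0
DEFAULT_N_ITER_TV = 100
DEFAULT_SIGMA_LOG = 2.0
DEFAULT_SIGMA_INIT_DOG = 2.0
DEFAULT_SIGMA_RATIO_DOG = 1.6
DEFAULT_SIGMA1_ST = 2.0
DEFAULT_SIGMA_AREA_ST = 2.0


@dataclass
class FeatureChannel:
    name: str
    source: str
    operator: str
    params: dict
    data: np.ndarray


def _warn_range(param: str, value) -> None:
    rng = PARAM_RANGES.get(param)
    if rng is None or value is None:
        return
    lo, hi, _ = rng
    if not (lo <= value <= hi):
        warnings.warn(
            f"{param}={value} is outside the recommended range [{lo}, {hi}]",
            stacklevel=3,
        )


def _as_float(grid) -> np.ndarray:
    return np.asarray(grid, dtype=np.float64)


def _gauss(grid, sigma, order=0, mode="reflect"):
    return ndimage.gaussian_filter(grid, sigma, order=order,
                                   mode=mode, truncate=_TRUNCATE)


def _channel(name, source, operator, params, data):
    return FeatureChannel(name=name, source=source, operator=operator,
                          params=params, data=data)


# ---------------------------------------------------------------------------
# operators


def gaussian(grid, sigma: float = DEFAULT_SIGMA_GAUSSIAN, *,
             boundary: str = "reflect", name: str = "gaussian",
             source: str = "__data__") -> FeatureChannel:
    """Isotropic 3D Gaussian smoothing (``boundary``: scipy mode name)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    _warn_range("sigma", sigma)
    data = _gauss(_as_float(grid), sigma, mode=boundary)
    return _channel(name, source, "gaussian", {"sigma": sigma}, data)


def total_variation(grid, lambda_tv: float = DEFAULT_LAMBDA_TV,
                    spacing_tv=(1.0, 1.0, 1.0), n_iter: int = DEFAULT_N_ITER_TV,
                    clamp=None, *, name: str = "total_variation",
                    source: str = "__data__") -> FeatureChannel:
    """TV denoising by Chambolle's dual projection scheme.

    ``lambda_tv`` is the denoising weight (larger = smoother), ``spacing_tv``
    weights the finite-difference gradient per (z, y, x) axis, and exactly
    ``n_iter`` fixed-point iterations are run (no early stopping, so the
    result is a pure function of the parameters).  ``clamp=(lo, hi)``
    truncates intensities to the interval *before* denoising; either bound
    may be None for an open side.
    """
    if lambda_tv <= 0:
        raise ValueError(f"lambda_tv must be > 0, got {lambda_tv}")
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    spacing_tv = np.broadcast_to(np.asarray(spacing_tv, dtype=np.float64), (3,)).copy()
    if (spacing_tv <= 0).any():
        raise ValueError(f"spacing_tv must be positive, got {spacing_tv}")
    _warn_range("lambda_tv", lambda_tv)
    _warn_range("n_iter", n_iter)
    for s in spacing_tv:
        _warn_range("spacing_tv", s)

    img = _as_float(grid).copy()
    if clamp is not None:
        lo, hi = clamp
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(f"clamp bounds out of order: {clamp}")
        img = np.clip(img, lo if lo is not None else -np.inf,
                      hi if hi is not None else np.inf)

    data = _tv_chambolle(img, weight=lambda_tv, spacing=spacing_tv, n_iter=n_iter)
    return _channel(name, source, "total_variation",
                    {"lambda_tv": lambda_tv, "spacing_tv": list(spacing_tv),
                     "n_iter": n_iter, "clamp": clamp}, data)


def _tv_chambolle(image, weight, spacing, n_iter):
    # dual formulation: p is the vector field, tau the fixed step size
    ndim = image.ndim
    p = np.zeros((ndim,) + image.shape)
    g = np.zeros_like(p)
    d = np.zeros_like(image)
    tau = 1.0 / (2.0 * ndim)
    out = image
    for it in range(n_iter):
        if it > 0:
            # divergence of p
            d = -p.sum(0)
            slices_d = [slice(None)] * ndim
            slices_p = [slice(None)] * (ndim + 1)
            for ax in range(ndim):
                slices_d[ax] = slice(1, None)
                slices_p[ax + 1] = slice(0, -1)
                slices_p[0] = ax
                d[tuple(slices_d)] += p[tuple(slices_p)]
                slices_d[ax] = slice(None)
                slices_p[ax + 1] = slice(None)
            out = image + d
        # axis-weighted forward differences of the current estimate
        slices_g = [slice(None)] * (ndim + 1)
        for ax in range(ndim):
            slices_g[ax + 1] = slice(0, -1)
            slices_g[0] = ax
            g[tuple(slices_g)] = np.diff(out, axis=ax) * spacing[ax]
            slices_g[ax + 1] = slice(None)
        norm = np.sqrt((g ** 2).sum(axis=0))[np.newaxis, ...]
        norm *= tau / weight
        norm += 1.0
        p -= tau * g
        p /= norm
    if n_iter > 0:
        d = -p.sum(0)
        slices_d = [slice(None)] * ndim
        slices_p = [slice(None)] * (ndim + 1)
        for ax in range(ndim):
            slices_d[ax] = slice(1, None)
            slices_p[ax + 1] = slice(0, -1)
            slices_p[0] = ax
            d[tuple(slices_d)] += p[tuple(slices_p)]
            slices_d[ax] = slice(None)
            slices_p[ax + 1] = slice(None)
        out = image + d
    return out


def threshold(grid, vmin: Optional[float] = None, vmax: Optional[float] = None, *,
              name: str = "threshold", source: str = "__data__") -> FeatureChannel:
    """Binary channel: 1 where vmin <= I <= vmax (omitted bound = open)."""
    if vmin is None and vmax is None:
        raise ValueError("threshold needs at least one of vmin, vmax")
    img = _as_float(grid)
    mask = np.ones(img.shape, dtype=bool)
    if vmin is not None:
        mask &= img >= vmin
    if vmax is not None:
        mask &= img <= vmax
    return _channel(name, source, "threshold", {"vmin": vmin, "vmax": vmax},
                    mask.astype(np.float64))


def gaussian_centering(grid, sigma: float = DEFAULT_SIGMA_CENTERING, *,
                       boundary: str = "reflect",
                       name: str = "gaussian_centering",
                       source: str = "__data__") -> FeatureChannel:
    """Local mean removal: I - G_sigma(I).

    With ``boundary="wrap"`` (periodic) the output mean is zero up to float
    error, since periodic Gaussian smoothing conserves the grid mean.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    _warn_range("sigma", sigma)
    img = _as_float(grid)
    data = img - _gauss(img, sigma, mode=boundary)
    return _channel(name, source, "gaussian_centering", {"sigma": sigma}, data)


def gaussian_normalization(grid, sigma: float = DEFAULT_SIGMA_NORMALIZATION, *,
                           name: str = "gaussian_normalization",
                           source: str = "__data__") -> FeatureChannel:
    """Local z-score: (I - G(I)) / sqrt(G((I - G(I))^2) + eps).

    eps = 1e-8 x global intensity variance keeps the output bounded and
    makes the channel invariant to affine intensity rescaling (a I + b,
    a > 0) up to eps effects.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    _warn_range("sigma", sigma)
    img = _as_float(grid)
    centered = img - _gauss(img, sigma)
    local_var = _gauss(centered ** 2, sigma)
    eps = 1e-8 * img.var()
    if eps == 0:  # constant input: define the output as all zeros
        eps = np.finfo(np.float64).tiny
    data = centered / np.sqrt(local_var + eps)
    return _channel(name, source, "gaussian_normalization", {"sigma": sigma}, data)


def laplacian_of_gaussian(grid, sigma_log: float = DEFAULT_SIGMA_LOG,
                          thresh_flag: bool = False, response: str = "bright", *,
                          name: str = "log", source: str = "__data__") -> FeatureChannel:
    """LoG blob response; ``response='bright'`` flips sign so bright blobs
    score positive; ``thresh_flag`` zeroes negative responses afterwards."""
    if sigma_log <= 0:
        raise ValueError(f"sigma_log must be > 0, got {sigma_log}")
    if response not in ("bright", "dark"):
        raise ValueError(f"response must be 'bright' or 'dark', got {response!r}")
    _warn_range("sigma_log", sigma_log)
    img = _as_float(grid)
    data = ndimage.gaussian_laplace(img, sigma_log, mode="reflect", truncate=_TRUNCATE)
    if response == "bright":
        data = -data  # bright blobs have negative raw LoG
    if thresh_flag:
        data = np.where(data > 0, data, 0.0)
    return _channel(name, source, "log",
                    {"sigma_log": sigma_log, "thresh_flag": thresh_flag,
                     "response": response}, data)


def difference_of_gaussians(grid, sigma_init: float = DEFAULT_SIGMA_INIT_DOG,
                            sigma_ratio: float = DEFAULT_SIGMA_RATIO_DOG, *,
                            name: str = "dog", source: str = "__data__") -> FeatureChannel:
    """G_sigma_init(I) - G_(sigma_init * sigma_ratio)(I)."""
    if sigma_init <= 0 or sigma_ratio <= 1:
        raise ValueError("need sigma_init > 0 and sigma_ratio > 1")
    _warn_range("sigma_init", sigma_init)
    _warn_range("sigma_ratio", sigma_ratio)
    img = _as_float(grid)
    data = _gauss(img, sigma_init) - _gauss(img, sigma_init * sigma_ratio)
    return _channel(name, source, "dog",
                    {"sigma_init": sigma_init, "sigma_ratio": sigma_ratio}, data)


def structure_tensor_det(grid, sigma1: float = DEFAULT_SIGMA1_ST,
                         sigma_area: float = DEFAULT_SIGMA_AREA_ST, *,
                         name: str = "structure_tensor_det",
                         source: str = "__data__") -> FeatureChannel:
    """Determinant of the 3x3 structure tensor.

    Gradients are Gaussian derivatives at scale ``sigma1``; the outer
    products are averaged at scale ``sigma_area``.  The determinant is
    non-negative up to numerical tolerance (the tensor is PSD).
    """
    if sigma1 <= 0 or sigma_area <= 0:
        raise ValueError("sigma1 and sigma_area must be > 0")
    _warn_range("sigma1", sigma1)
    _warn_range("sigma_area", sigma_area)
    img = _as_float(grid)
    grads = [
        _gauss(img, sigma1, order=[int(ax == a) for a in range(3)])
        for ax in range(3)
    ]
    # upper triangle of the averaged tensor
    J = {}
    for i in range(3):
        for j in range(i, 3):
            J[(i, j)] = _gauss(grads[i] * grads[j], sigma_area)
    det = (J[(0, 0)] * (J[(1, 1)] * J[(2, 2)] - J[(1, 2)] ** 2)
           - J[(0, 1)] * (J[(0, 1)] * J[(2, 2)] - J[(1, 2)] * J[(0, 2)])
           + J[(0, 2)] * (J[(0, 1)] * J[(1, 2)] - J[(1, 1)] * J[(0, 2)]))
    return _channel(name, source, "structure_tensor_det",
                    {"sigma1": sigma1, "sigma_area": sigma_area}, det)


OPERATORS = {
    "gaussian": gaussian,
    "total_variation": total_variation,
    "threshold": threshold,
    "gaussian_centering": gaussian_centering,
    "gaussian_normalization": gaussian_normalization,
    "log": laplacian_of_gaussian,
    "dog": difference_of_gaussians,
    "structure_tensor_det": structure_tensor_det,
}


# ---------------------------------------------------------------------------
# queue


def compute_queue(ws, specs) -> dict:
    """Compute a list of channel specs in dependency order.

    Each spec is a mapping with keys ``name``, ``operator``, optional
    ``source`` (default raw data) and ``params``.  A spec may consume a
    channel defined later in the list; cycles and missing sources are
    errors.  Recomputing a channel drops channels that depend on it.
    """
    specs = list(specs)
    by_name = {}
    for spec in specs:
        name = spec["name"]
        if name in by_name:
            raise ValueError(f"duplicate channel name {name!r} in queue")
        by_name[name] = spec

    # topological order over the queue's internal dependencies
    order, state = [], {}

    def visit(name):
        if state.get(name) == "done":
            return
        if state.get(name) == "active":
            raise ValueError(f"cyclic channel dependency involving {name!r}")
        state[name] = "active"
        src = by_name[name].get("source", "__data__")
        if src in by_name:
            visit(src)
        elif src not in ("__data__", "raw", "raw_data") and src not in ws.channels:
            raise ValueError(f"channel {name!r} references undefined source {src!r}")
        state[name] = "done"
        order.append(name)

    for spec in specs:
        visit(spec["name"])

    # recomputation invalidates dependents already in the workspace
    recomputed = set(by_name)
    changed = True
    while changed:
        changed = False
        for cname, ch in list(ws.channels.items()):
            if ch.source in recomputed and cname not in recomputed:
                del ws.channels[cname]
                recomputed.add(cname)
                changed = True

    computed = {}
    for name in order:
        spec = by_name[name]
        op = spec["operator"]
        if op not in OPERATORS:
            raise ValueError(f"unknown operator {op!r}; use one of {sorted(OPERATORS)}")
        src = spec.get("source", "__data__")
        grid = computed[src].data if src in computed else ws.channel_data(src)
        channel = OPERATORS[op](grid, name=name, source=src, **spec.get("params", {}))
        computed[name] = channel
        ws.channels[name] = channel
    return computed


def discrete_total_variation(grid, spacing=(1.0, 1.0, 1.0)) -> float:
    """Isotropic discrete TV: sum of axis-weighted gradient magnitudes."""
    grid = _as_float(grid)
    sq = np.zeros(grid.shape)
    for ax in range(grid.ndim):
        d = np.diff(grid, axis=ax) * spacing[ax]
        pad = [(0, 1) if a == ax else (0, 0) for a in range(grid.ndim)]
        sq += np.pad(d, pad) ** 2
    return float(np.sqrt(sq).sum())
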