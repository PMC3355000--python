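"""Five-layer head segmentation from T1-like volumes.

The pipeline follows the two-step design used for the head model:

1. **Geometry step** — variational level sets (distance-regularized, so no
   re-initialization is needed) contour the scalp outer surface, the
   scalp/skull interface and the inner skull wall on each axial slice;
   region growing labels the scalp (1) and skull (2) rings.
2. **Intensity step** — a mixture-of-Gaussians model fitted to the
   intracranial intensities assigns CSF (3), gray matter (4) and white
   matter (5) by maximum posterior probability.

The level-set energy is ``E(phi) = mu*P(phi) + lambda*L_g(phi) + nu*A_g(phi)``
with the signed-distance penalty ``P``, the edge-weighted contour length
``L_g`` and area ``A_g``; ``g`` is the edge indicator
``1 / (1 + |grad(G_sigma * I)|^2)``.  The sign convention is phi < 0 inside
the contour, so nu > 0 shrinks and nu < 0 expands the enclosed region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import CSF, GRAY, LabelVolume, SCALP, SKULL, ScalarVolume, WHITE

__all__ = [
    "LevelSetParams",
    "MixtureModel",
    "RegionGrowSpec",
    "SegmentationParams",
    "classify_max_prob",
    "distance_penalty",
    "edge_indicator",
    "evolve_level_set",
    "extract_zero_level_region",
    "fit_mog",
    "phi_from_mask",
    "region_grow",
    "segment_five_layers",
]


# --------------------------------------------------------------------------
# level sets
# --------------------------------------------------------------------------

@dataclass
class LevelSetParams:
    """Weights and numerics of the variational level-set evolution.

    ``tau_step * mu_pen < 0.25`` is required for stability of the explicit
    scheme; the Dirac/Heaviside regularization width ``eps_reg`` is in
    pixels.  ``nu_area > 0`` shrinks the enclosed (phi < 0) region, negative
    values expand it.
    """

    mu_pen: float = 0.04       # signed-distance penalty weight (mu > 0)
    lambda_len: float = 5.0    # edge-weighted length weight (lambda > 0)
    nu_area: float = 1.5       # edge-weighted area weight (sign = direction)
    sigma_gauss: float = 1.5   # Gaussian kernel scale of the edge indicator
    tau_step: float = 5.0      # explicit time step
    eps_reg: float = 1.5       # Dirac/Heaviside regularization width (px)
    n_iter: int = 300          # iteration budget
    tol: float = 1.0           # stop when the inside region changes < tol px
    check_every: int = 10      # interval (iterations) between stop checks

    def __post_init__(self) -> None:
        if self.mu_pen <= 0 or self.lambda_len <= 0:
            raise ValueError("mu_pen and lambda_len must be > 0")
        if self.tau_step * self.mu_pen >= 0.25:
            raise ValueError(
                f"stability requires tau_step*mu_pen < 0.25, got "
                f"{self.tau_step * self.mu_pen:.3f}"
            )
        if self.eps_reg <= 0 or self.sigma_gauss <= 0:
            raise ValueError("eps_reg and sigma_gauss must be > 0")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")


def edge_indicator(img: np.ndarray, sigma_gauss: float) -> np.ndarray:
    """Edge indicator ``g = 1 / (1 + |grad(G_sigma * I)|^2)``.

    Gaussian smoothing followed by central-difference gradients; values lie
    in (0, 1] and equal 1 exactly where the smoothed gradient vanishes.
    """
    if sigma_gauss <= 0:
        raise ValueError("sigma_gauss must be > 0")
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    smoothed = ndimage.gaussian_filter(img, sigma_gauss, mode="nearest")
    grads = np.gradient(smoothed)
    sq = sum(gr * gr for gr in grads)
    return 1.0 / (1.0 + sq)


def _dirac(x: np.ndarray, eps: float) -> np.ndarray:
    """Cosine-regularized Dirac delta, supported on |x| <= eps."""
    out = np.zeros_like(x)
    inside = np.abs(x) <= eps
    out[inside] = (1.0 + np.cos(np.pi * x[inside] / eps)) / (2.0 * eps)
    return out


def distance_penalty(phi: np.ndarray) -> float:
    """Signed-distance deviation energy ``P(phi) = 0.5 * int (|grad phi| - 1)^2``.

    Vanishes (up to discretization) on an exact signed distance field.
    """
    grads = np.gradient(np.asarray(phi, dtype=np.float64))
    mag = np.sqrt(sum(gr * gr for gr in grads))
    return float(0.5 * np.sum((mag - 1.0) ** 2))


def phi_from_mask(mask: np.ndarray, c0: float = 2.0) -> np.ndarray:
    """Binary-step initial level-set field: -c0 inside the mask, +c0 outside."""
    return np.where(mask, -c0, c0).astype(np.float64)


def evolve_level_set(
    img: np.ndarray, phi0: np.ndarray, params: LevelSetParams
) -> np.ndarray:
    """Evolve the level-set field under the regularized variational flow.

    Gradient descent on the energy above with the cosine-regularized delta;
    the distance penalty keeps phi close to a signed distance function, so no
    re-initialization step is performed.  Stops after ``n_iter`` iterations
    or once the enclosed region changes by fewer than ``tol`` pixels between
    checks.  Raises on numerical divergence, reporting the iteration.
    """
    phi = np.asarray(phi0, dtype=np.float64).copy()
    if not np.all(np.isfinite(phi)):
        raise ValueError("phi0 contains non-finite values")
    if params.n_iter == 0:
        return phi
    g = edge_indicator(img, params.sigma_gauss)
    g_grads = np.gradient(g)
    prev_area = int(np.count_nonzero(phi < 0))
    err = np.errstate(over="ignore", invalid="ignore")  # divergence is caught
    with err:
        return _evolve_loop(phi, g, g_grads, params, prev_area)


def _evolve_loop(phi, g, g_grads, params, prev_area):
    for it in range(params.n_iter):
        grads = np.gradient(phi)
        mag = np.sqrt(sum(gr * gr for gr in grads)) + 1e-10
        normals = [gr / mag for gr in grads]
        curvature = sum(np.gradient(n, axis=k) for k, n in enumerate(normals))
        dist_reg = ndimage.laplace(phi, mode="nearest") - curvature
        delta = _dirac(phi, params.eps_reg)
        edge_term = delta * (sum(gg * n for gg, n in zip(g_grads, normals))
                             + g * curvature)
        area_term = delta * g
        phi += params.tau_step * (
            params.mu_pen * dist_reg
            + params.lambda_len * edge_term
            + params.nu_area * area_term
        )
        if not np.all(np.isfinite(phi)):
            raise FloatingPointError(
                f"level-set evolution diverged at iteration {it}"
            )
        if (it + 1) % params.check_every == 0:
            area = int(np.count_nonzero(phi < 0))
            if abs(area - prev_area) < params.tol:
                break
            prev_area = area
    return phi


def extract_zero_level_region(phi: np.ndarray) -> tuple[np.ndarray, str]:
    """Binary mask of the region enclosed by the zero level set.

    Negative phi is inside.  Returns ``(mask, status)`` where status is
    ``"ok"`` when the field changes sign and ``"no-interface"`` when the
    mask is empty or full.
    """
    phi = np.asarray(phi, dtype=np.float64)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phi contains non-finite values")
    mask = phi < 0
    n_in = int(np.count_nonzero(mask))
    status = "ok" if 0 < n_in < mask.size else "no-interface"
    return mask, status


# --------------------------------------------------------------------------
# region growing
# --------------------------------------------------------------------------

@dataclass
class RegionGrowSpec:
    """Seeds (in labeling order) and pixel connectivity for region growing.

    Connectivity: 4 or 8 for 2-D grids, 6 or 26 for 3-D grids.
    """

    seeds: list[tuple[int, ...]]
    connectivity: int = 4


_CONN_STRUCTURES = {(2, 4): 1, (2, 8): 2, (3, 6): 1, (3, 26): 3}


def region_grow(mask: np.ndarray, spec: RegionGrowSpec) -> np.ndarray:
    """Flood each seed's connected component; label in seed order (1, 2, ...).

    Foreground not reached by any seed stays 0.  When two seeds share a
    component, the first seed's label wins.  Seeds on background raise.
    """
    mask = np.asarray(mask, dtype=bool)
    key = (mask.ndim, spec.connectivity)
    if key not in _CONN_STRUCTURES:
        raise ValueError(
            f"connectivity {spec.connectivity} invalid for {mask.ndim}-D grids"
        )
    structure = ndimage.generate_binary_structure(mask.ndim, _CONN_STRUCTURES[key])
    components, _ = ndimage.label(mask, structure=structure)
    out = np.zeros(mask.shape, dtype=np.int32)
    claimed: set[int] = set()
    for i, seed in enumerate(spec.seeds, start=1):
        seed = tuple(int(c) for c in seed)
        if not mask[seed]:
            raise ValueError(f"seed {seed} lies on background")
        comp = int(components[seed])
        if comp in claimed:
            continue  # first seed's label wins
        out[components == comp] = i
        claimed.add(comp)
    return out


# --------------------------------------------------------------------------
# mixture of Gaussians
# --------------------------------------------------------------------------

@dataclass
class MixtureModel:
    """1-D Gaussian mixture: per component mean, variance and mixing weight.

    ``component_tissue`` maps component index -> tissue code once components
    have been assigned to tissues; ``loglik_trace`` records the (monotone)
    EM log-likelihood per iteration.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    collapsed: bool = False
    component_tissue: dict[int, int] | None = None

    @property
    def n_components(self) -> int:
        return len(self.means)

    def log_component_densities(self, y: np.ndarray) -> np.ndarray:
        """Weighted log densities, shape (K, len(y))."""
        y = np.asarray(y, dtype=np.float64)
        mu = self.means[:, None]
        var = self.variances[:, None]
        return (
            np.log(self.weights[:, None])
            - 0.5 * np.log(2.0 * np.pi * var)
            - 0.5 * (y[None, :] - mu) ** 2 / var
        )


def fit_mog(
    samples: np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor_rel: float = 1e-8,
) -> MixtureModel:
    """Fit a 1-D mixture of Gaussians by EM.

    The log-likelihood is non-decreasing across iterations; convergence is
    declared when its change drops below ``tol``.  A component whose
    variance collapses below ``var_floor_rel`` times the data variance is
    floored and flagged via ``collapsed``.  With one component the fit
    equals the closed-form sample mean and biased sample variance.
    """
    y = np.asarray(samples, dtype=np.float64).ravel()
    if len(np.unique(y)) < n_components:
        raise ValueError(
            f"need at least {n_components} distinct sample values, "
            f"got {len(np.unique(y))}"
        )
    n = y.size
    total_var = max(float(np.var(y)), 1e-30)
    floor = var_floor_rel * total_var
    rng = np.random.default_rng(seed)

    def _em(init_means: np.ndarray):
        means = init_means + 1e-9 * np.std(y) * rng.standard_normal(n_components)
        variances = np.full(n_components, total_var)
        weights = np.full(n_components, 1.0 / n_components)
        model = MixtureModel(means, variances, weights)
        trace: list[float] = []
        collapsed = False
        converged = False
        for _ in range(max_iter):
            log_dens = model.log_component_densities(y)  # (K, n)
            log_norm = np.logaddexp.reduce(log_dens, axis=0)
            trace.append(float(np.sum(log_norm)))
            resp = np.exp(log_dens - log_norm[None, :])  # responsibilities
            nk = np.maximum(resp.sum(axis=1), 1e-300)
            means = resp @ y / nk
            variances = (resp * (y[None, :] - means[:, None]) ** 2
                         ).sum(axis=1) / nk
            if np.any(variances < floor):
                collapsed = True
                variances = np.maximum(variances, floor)
            weights = nk / n
            model = MixtureModel(means, variances, weights)
            if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        return model, trace, collapsed, converged

    # EM converges to local optima, so start from several deterministic
    # initializations and keep the best likelihood
    qs = (np.arange(n_components) + 0.5) / n_components
    inits = [np.quantile(y, qs),
             np.linspace(y.min(), y.max(), n_components + 2)[1:-1]]
    best = None
    for init in inits:
        fit = _em(np.asarray(init, dtype=np.float64))
        if best is None or fit[1][-1] > best[1][-1]:
            best = fit
    model, trace, collapsed, converged = best
    order = np.argsort(model.means)  # ascending-mean component order
    return MixtureModel(
        means=model.means[order],
        variances=model.variances[order],
        weights=model.weights[order],
        loglik_trace=np.asarray(trace),
        converged=converged,
        collapsed=collapsed,
    )


def classify_max_prob(
    img: ScalarVolume | np.ndarray,
    model: MixtureModel,
    mask: np.ndarray,
) -> np.ndarray:
    """Assign each masked voxel the tissue of its maximum-posterior component.

    Requires ``model.component_tissue``.  Exact posterior ties break toward
    the lower tissue code.  Unmasked voxels stay 0.
    """
    if model.component_tissue is None:
        raise ValueError("model.component_tissue mapping is not set")
    data = img.intensities if isinstance(img, ScalarVolume) else np.asarray(img)
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite intensities")
    mask = np.asarray(mask, dtype=bool)
    y = data[mask].astype(np.float64)
    # evaluate components in ascending tissue-code order so argmax's
    # first-wins rule implements the lower-code tie-break
    order = sorted(range(model.n_components),
                   key=lambda k: model.component_tissue[k])
    sub = MixtureModel(
        means=model.means[order],
        variances=model.variances[order],
        weights=model.weights[order],
    )
    codes = np.array([model.component_tissue[k] for k in order])
    best = np.argmax(sub.log_component_densities(y), axis=0)
    out = np.zeros(data.shape, dtype=np.uint8)
    out[mask] = codes[best]
    return out


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    """Parameters of the full five-layer segmentation pipeline."""

    level_set: LevelSetParams = field(default_factory=LevelSetParams)
    border_margin_px: int = 3        # initial contour inset from the image border
    erode_px: int = 2                # inset of each successive initial contour
    min_head_area_px: int = 64       # slices below this are treated as air
    mog_seed: int = 0
    mog_tol: float = 1e-7
    mog_max_iter: int = 300
    t1_ordering: tuple[int, int, int] = (CSF, GRAY, WHITE)  # ascending mean


def _contour_mask(img2d: np.ndarray, init_mask: np.ndarray,
                  params: LevelSetParams) -> np.ndarray:
    """Shrink a contour from ``init_mask`` onto the nearest strong edge."""
    phi = evolve_level_set(img2d, phi_from_mask(init_mask), params)
    mask, _ = extract_zero_level_region(phi)
    return ndimage.binary_fill_holes(mask)


def _masked_fill(img2d: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Replace intensities outside ``region`` by the median of its rim.

    Removes the image edge along the region's own boundary so an inward
    level set locks onto the *next* interface instead of being recaptured
    by the one already found.
    """
    core = ndimage.binary_erosion(region)
    band = core & ~ndimage.binary_erosion(region, iterations=3)
    if not band.any():
        band, core = region, region
    fill = float(np.median(img2d[band]))
    out = img2d.copy()
    out[~core] = fill  # the (possibly contaminated) rim is flattened too
    return out


def _robust_stats(values: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based sigma (contamination-tolerant class statistics)."""
    med = float(np.median(values))
    sigma = 1.4826 * float(np.median(np.abs(values - med)))
    return med, max(sigma, 1e-3)


def _log_gauss(y: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -np.log(sd) - 0.5 * ((y - mean) / sd) ** 2


# in-plane (per-slice) structuring element for 3-D masks assembled from
# 2-D slice segmentations: morphology must not couple neighbouring slices
_SLICE_STRUCT = np.zeros((3, 3, 3), dtype=bool)
_SLICE_STRUCT[:, :, 1] = ndimage.generate_binary_structure(2, 1)


def _erode2d(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    return ndimage.binary_erosion(mask, structure=_SLICE_STRUCT,
                                  iterations=iterations)


def _dilate2d(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=_SLICE_STRUCT,
                                   iterations=iterations)


def _fill2d(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_fill_holes(mask, structure=_SLICE_STRUCT)


def segment_five_layers(
    img: ScalarVolume, params: SegmentationParams | None = None
) -> LabelVolume:
    """Segment a T1-like volume into the five-layer head model.

    Step 1 (geometry): per axial slice, a level set shrinks from the image
    border onto the scalp outer contour; two further level sets — each run
    on an image whose already-contoured exterior has been flattened so the
    previous edge no longer attracts — lock onto the scalp/skull interface
    and the inner skull wall.  The inner-wall contour is then refined to
    voxel precision by maximum-posterior reclassification of a narrow band
    (skull versus intracranial intensity models), and region growing labels
    the scalp (1) and skull (2) rings.

    Step 2 (intensity): a three-component Gaussian mixture fitted to the
    intracranial intensities assigns CSF (3), gray (4) and white matter (5)
    by maximum posterior, components mapped to tissues by ascending mean
    under the T1 ordering (CSF darkest, then gray, then white matter).
    """
    params = params or SegmentationParams()
    data = img.intensities
    nx, ny, nz = data.shape
    head3 = np.zeros(data.shape, dtype=bool)
    inner1_3 = np.zeros(data.shape, dtype=bool)
    inner2_3 = np.zeros(data.shape, dtype=bool)
    found_any = False

    for z in range(nz):
        sl = data[:, :, z]
        border_init = np.zeros((nx, ny), dtype=bool)
        m = params.border_margin_px
        border_init[m:-m, m:-m] = True
        head = _contour_mask(sl, border_init, params.level_set)
        if head.sum() < params.min_head_area_px:
            continue
        found_any = True
        shrink = ndimage.binary_erosion(head, iterations=params.erode_px)
        inner1 = _contour_mask(_masked_fill(sl, head), shrink,
                               params.level_set) & shrink
        shrink1 = ndimage.binary_erosion(inner1, iterations=params.erode_px)
        inner2 = _contour_mask(_masked_fill(sl, inner1), shrink1,
                               params.level_set) & shrink1
        head3[:, :, z] = head
        inner1_3[:, :, z] = inner1
        inner2_3[:, :, z] = inner2

    if not found_any:
        raise ValueError(
            "level set found no closed head contour on any slice "
            "(is the image constant or head-free?)"
        )

    # class statistics from the cores of the rough rings
    scalp_ring = head3 & ~inner1_3
    skull_ring = inner1_3 & ~inner2_3
    core = _erode2d(skull_ring)
    mu_skull, sd_skull = _robust_stats(
        data[core if core.any() else skull_ring])
    core = _erode2d(scalp_ring)
    mu_scalp, sd_scalp = _robust_stats(
        data[core if core.any() else scalp_ring])

    mog_core = _erode2d(inner2_3)
    if not mog_core.any():
        mog_core = inner2_3
    model = fit_mog(data[mog_core], n_components=3, seed=params.mog_seed,
                    tol=params.mog_tol, max_iter=params.mog_max_iter)
    model.component_tissue = {
        k: code for k, code in enumerate(params.t1_ordering)
    }  # components already sorted by ascending mean

    # refine the outer scalp contour: reclassify a band around the rough
    # head edge as scalp vs background
    outside = ~_dilate2d(head3, iterations=2)
    if outside.any():
        mu_air, sd_air = _robust_stats(data[outside])
        edge = head3 ^ _erode2d(head3)
        band = _dilate2d(edge, iterations=params.erode_px)
        y = data[band]
        is_scalp = np.zeros(data.shape, dtype=bool)
        is_scalp[band] = (_log_gauss(y, mu_scalp, sd_scalp)
                          > _log_gauss(y, mu_air, sd_air))
        head3 = _fill2d((head3 & ~band) | (band & is_scalp))

    # refine the inner skull wall: reclassify a band around the rough
    # contour as skull vs the two shallowest intracranial components
    edge = inner2_3 ^ _erode2d(inner2_3)
    band = _dilate2d(edge, iterations=params.erode_px + 1) & head3
    y = data[band]
    skull_ll = _log_gauss(y, mu_skull, sd_skull)
    intra_ll = np.maximum(
        _log_gauss(y, model.means[0], np.sqrt(model.variances[0])),
        _log_gauss(y, model.means[1], np.sqrt(model.variances[1])),
    )
    is_intra = np.zeros(data.shape, dtype=bool)
    is_intra[band] = intra_ll > skull_ll
    intracranial = _fill2d((inner2_3 & ~band) | (band & is_intra))

    # scalp/skull: posterior classification of the annulus, made spatially
    # coherent by region growing from a scalp and a skull seed
    annulus = head3 & ~intracranial
    y = data[annulus]
    scalp_like = np.zeros(data.shape, dtype=bool)
    scalp_like[annulus] = (_log_gauss(y, mu_scalp, sd_scalp)
                           >= _log_gauss(y, mu_skull, sd_skull))
    labels = np.zeros(data.shape, dtype=np.uint8)
    scalp_mask = annulus & scalp_like
    skull_mask = annulus & ~scalp_like
    for mask, code in ((scalp_mask, SCALP), (skull_mask, SKULL)):
        if not mask.any():
            continue
        idx = np.argwhere(mask)
        seed = tuple(idx[np.argmax(np.abs(idx - np.array(mask.shape) / 2.0)
                                   .sum(axis=1))])
        grown = region_grow(mask, RegionGrowSpec(seeds=[seed], connectivity=26))
        labels[grown == 1] = code
        labels[mask & (grown == 0)] = code  # isolated speckles keep their class

    inner_labels = classify_max_prob(data, model, intracranial)
    labels[intracranial] = inner_labels[intracranial]
    return LabelVolume(labels, voxel_size=img.voxel_size, origin=img.origin)
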