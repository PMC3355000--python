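"""Segmentation: edge indicator, level sets, region growing, MOG, pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from nirsim import LabelVolume, make_synthetic_mri
from nirsim.segmentation import (
    LevelSetParams,
    MixtureModel,
    RegionGrowSpec,
    classify_max_prob,
    distance_penalty,
    edge_indicator,
    evolve_level_set,
    extract_zero_level_region,
    fit_mog,
    phi_from_mask,
    region_grow,
    segment_five_layers,
)
from nirsim.volumes import CSF, GRAY, WHITE

from conftest import dice


# -- edge indicator ---------------------------------------------------------

def test_edge_indicator_constant_image_is_one():
    g = edge_indicator(np.full((32, 32), 7.0), sigma_gauss=1.5)
    assert np.all(g == 1.0)


def test_edge_indicator_minimum_on_step_edge():
    img = np.zeros((32, 64))
    img[:, 32:] = 255.0
    g = edge_indicator(img, sigma_gauss=1.5)
    cols = g.min(axis=0)
    assert abs(int(np.argmin(cols)) - 32) <= 1
    assert g.min() < 0.01
    assert g.max() <= 1.0


def test_edge_indicator_linear_ramp_closed_form():
    """On a ramp of slope a (invariant under smoothing), g = 1/(1+a^2)."""
    a = 3.0
    img = a * np.arange(64, dtype=float)[None, :].repeat(8, axis=0)
    g = edge_indicator(img, sigma_gauss=0.5)
    interior = g[:, 10:-10]
    assert np.allclose(interior, 1.0 / (1.0 + a * a), rtol=1e-3)


def test_edge_indicator_rejects_non_finite():
    img = np.zeros((8, 8))
    img[3, 3] = np.nan
    with pytest.raises(ValueError):
        edge_indicator(img, 1.0)


# -- level-set evolution ----------------------------------------------------

def _disk_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def _signed_distance(mask):
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return np.where(mask, -inside, outside).astype(float)


def _signed_distance_subpixel(mask):
    """SDF with the interface half a pixel outside the last inside pixel,
    so |grad phi| = 1 holds across the boundary (values ..., -1.5, -0.5,
    +0.5, ...)."""
    inside = ndimage.distance_transform_edt(mask) - 0.5
    outside = ndimage.distance_transform_edt(~mask) - 0.5
    return np.where(mask, -inside, outside).astype(float)


def test_zero_iterations_returns_initial_field():
    phi0 = np.random.default_rng(0).standard_normal((16, 16))
    params = LevelSetParams(n_iter=0)
    out = evolve_level_set(np.zeros((16, 16)), phi0, params)
    assert np.array_equal(out, phi0)


def test_signed_distance_is_fixed_point_of_penalty_flow():
    """With lambda, nu inactive the distance penalty leaves an SDF unchanged
    up to discretization."""
    phi0 = _signed_distance_subpixel(_disk_mask((64, 64), (32, 32), 15.0))
    params = LevelSetParams(mu_pen=0.04, lambda_len=1e-12, nu_area=0.0,
                            n_iter=50, tol=0.0, check_every=10**9)
    out = evolve_level_set(np.zeros((64, 64)), phi0, params)
    # judge near the interface: the SDF kinks (disk centre ridge, image
    # corners) are genuine discretization hot spots of the penalty flow
    band = np.abs(phi0) < 10.0
    assert np.abs(out - phi0)[band].max() < 0.75  # lattice kinks relax a little
    mask0, _ = extract_zero_level_region(phi0)
    mask1, _ = extract_zero_level_region(out)
    assert (mask0 ^ mask1).sum() < 10


def test_penalty_energy_small_on_exact_sdf():
    phi = _signed_distance_subpixel(_disk_mask((64, 64), (32, 32), 20.0))
    per_pixel = distance_penalty(phi) / phi.size
    assert per_pixel < 0.02


def test_expanding_contour_recovers_disk_boundary():
    """Expansion (nu < 0) from a small seed locks onto a radius-20 disk."""
    mask = _disk_mask((80, 80), (40, 40), 20.0)
    img = np.where(mask, 200.0, 0.0)
    phi0 = phi_from_mask(_disk_mask((80, 80), (40, 40), 5.0))
    params = LevelSetParams(nu_area=-1.5, n_iter=600, tol=0.0,
                            check_every=10**9)
    phi = evolve_level_set(img, phi0, params)
    got, status = extract_zero_level_region(phi)
    assert status == "ok"
    # the continuous zero-level contour lies within 1 px of the true circle
    from skimage import measure
    contour = max(measure.find_contours(phi, 0.0), key=len)
    radii = np.hypot(contour[:, 0] - 40.0, contour[:, 1] - 40.0)
    assert np.abs(radii - 20.0).max() <= 1.0


def test_divergence_reported_with_iteration():
    params = LevelSetParams.__new__(LevelSetParams)  # bypass stability guard
    for name, val in dict(mu_pen=50.0, lambda_len=5.0, nu_area=1.5,
                          sigma_gauss=1.5, tau_step=50.0, eps_reg=1.5,
                          n_iter=200, tol=0.0, check_every=10**9).items():
        setattr(params, name, val)
    img = np.random.default_rng(0).random((32, 32)) * 255
    phi0 = phi_from_mask(_disk_mask((32, 32), (16, 16), 8.0))
    with pytest.raises(FloatingPointError, match="iteration"):
        evolve_level_set(img, phi0, params)


def test_stability_guard_rejects_large_time_step():
    with pytest.raises(ValueError, match="0.25"):
        LevelSetParams(mu_pen=0.2, tau_step=5.0)


# -- zero-level region ------------------------------------------------------

def test_zero_level_region_circle_area():
    phi = _signed_distance(_disk_mask((128, 128), (64, 64), 30.0))
    mask, status = extract_zero_level_region(phi)
    assert status == "ok"
    assert abs(mask.sum() - np.pi * 30.0 ** 2) / (np.pi * 30.0 ** 2) < 0.02


def test_zero_level_region_no_interface():
    mask, status = extract_zero_level_region(np.ones((16, 16)))
    assert status == "no-interface"
    assert not mask.any()


def test_zero_level_region_sign_flip_complements():
    phi = _signed_distance(_disk_mask((64, 64), (32, 32), 10.0))
    phi[phi == 0] = -1e-9  # keep the boundary on one side under the flip
    m1, _ = extract_zero_level_region(phi)
    m2, _ = extract_zero_level_region(-phi)
    assert np.array_equal(m1, ~m2)


# -- region growing ---------------------------------------------------------

def _bfs_flood(mask, seed, connectivity):
    """Independent breadth-first flood oracle."""
    from collections import deque
    offsets = []
    ndim = mask.ndim
    for delta in np.ndindex(*(3,) * ndim):
        d = np.array(delta) - 1
        manh = np.abs(d).sum()
        if manh == 0:
            continue
        if connectivity in (4, 6) and manh > 1:
            continue
        offsets.append(tuple(d))
    seen = np.zeros(mask.shape, dtype=bool)
    queue = deque([tuple(seed)])
    seen[tuple(seed)] = True
    while queue:
        p = queue.popleft()
        for off in offsets:
            q = tuple(np.array(p) + off)
            if any(c < 0 or c >= s for c, s in zip(q, mask.shape)):
                continue
            if mask[q] and not seen[q]:
                seen[q] = True
                queue.append(q)
    return seen


def test_region_grow_single_component():
    mask = np.zeros((16, 16), dtype=bool)
    mask[2:8, 2:8] = True
    out = region_grow(mask, RegionGrowSpec(seeds=[(3, 3)], connectivity=4))
    assert np.array_equal(out == 1, mask)


def test_region_grow_two_components_ordered_labels():
    mask = np.zeros((16, 16), dtype=bool)
    mask[1:5, 1:5] = True
    mask[10:14, 10:14] = True
    out = region_grow(mask, RegionGrowSpec(seeds=[(2, 2), (11, 11)],
                                           connectivity=4))
    assert np.all(out[1:5, 1:5] == 1)
    assert np.all(out[10:14, 10:14] == 2)
    assert set(np.unique(out)) == {0, 1, 2}


def test_region_grow_first_seed_wins_shared_component():
    mask = np.ones((8, 8), dtype=bool)
    out = region_grow(mask, RegionGrowSpec(seeds=[(0, 0), (7, 7)],
                                           connectivity=4))
    assert np.all(out == 1)


def test_region_grow_seed_on_background_raises():
    mask = np.zeros((8, 8), dtype=bool)
    mask[0, 0] = True
    with pytest.raises(ValueError, match=r"\(4, 4\)"):
        region_grow(mask, RegionGrowSpec(seeds=[(4, 4)]))


@pytest.mark.parametrize("connectivity", [6, 26])
@pytest.mark.parametrize("seed", range(4))
def test_region_grow_matches_bfs_oracle_random_masks(connectivity, seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((32, 32, 32)) < 0.35
    idx = np.argwhere(mask)
    start = tuple(idx[rng.integers(len(idx))])
    out = region_grow(mask, RegionGrowSpec(seeds=[start],
                                           connectivity=connectivity))
    oracle = _bfs_flood(mask, start, connectivity)
    assert np.array_equal(out == 1, oracle)


# -- mixture of Gaussians ---------------------------------------------------

def test_mog_single_component_closed_form():
    rng = np.random.default_rng(0)
    y = rng.normal(3.0, 2.0, 5000)
    model = fit_mog(y, 1)
    assert model.means[0] == pytest.approx(y.mean(), abs=1e-12)
    assert model.variances[0] == pytest.approx(y.var(), abs=1e-12)
    assert model.weights[0] == 1.0


def test_mog_recovers_well_separated_components():
    rng = np.random.default_rng(1)
    y = np.concatenate([rng.normal(0.0, 1.0, 10_000),
                        rng.normal(8.0, 1.0, 10_000)])
    model = fit_mog(y, 2, seed=0)
    assert model.means[0] == pytest.approx(0.0, abs=0.05)
    assert model.means[1] == pytest.approx(8.0, rel=0.02)
    assert np.allclose(model.weights, 0.5, atol=0.02)


def test_mog_loglik_monotone_non_decreasing():
    rng = np.random.default_rng(2)
    y = np.concatenate([rng.normal(0, 1, 2000), rng.normal(3, 2, 2000)])
    model = fit_mog(y, 2, seed=0, tol=0.0, max_iter=200)
    diffs = np.diff(model.loglik_trace)
    assert np.all(diffs >= -1e-8 * np.abs(model.loglik_trace[:-1]))


def test_mog_matches_sklearn_reference():
    """Independent cross-check of the EM fit against scikit-learn."""
    from sklearn.mixture import GaussianMixture
    rng = np.random.default_rng(3)
    y = np.concatenate([rng.normal(-2, 0.5, 4000), rng.normal(2, 1.5, 6000)])
    ours = fit_mog(y, 2, seed=0, tol=1e-10)
    ref = GaussianMixture(2, random_state=0, n_init=3, tol=1e-10,
                          reg_covar=0).fit(y[:, None])
    order = np.argsort(ref.means_.ravel())
    assert np.allclose(ours.means, ref.means_.ravel()[order], atol=0.02)
    assert np.allclose(np.sqrt(ours.variances),
                       np.sqrt(ref.covariances_.ravel()[order]), atol=0.02)


def test_mog_requires_enough_distinct_values():
    with pytest.raises(ValueError, match="distinct"):
        fit_mog(np.array([1.0, 1.0, 1.0, 2.0]), 3)


# -- maximum-probability classification ------------------------------------

def _toy_model():
    model = MixtureModel(
        means=np.array([10.0, 20.0, 30.0]),
        variances=np.array([1.0, 1.0, 1.0]),
        weights=np.array([1 / 3, 1 / 3, 1 / 3]),
    )
    model.component_tissue = {0: CSF, 1: GRAY, 2: WHITE}
    return model


def test_classify_at_component_mean():
    img = np.full((2, 2, 1), 20.0)
    out = classify_max_prob(img, _toy_model(), np.ones((2, 2, 1), dtype=bool))
    assert np.all(out == GRAY)


def test_classify_tie_breaks_to_lower_code():
    img = np.full((1, 1, 1), 15.0)  # equidistant between CSF and GM components
    out = classify_max_prob(img, _toy_model(), np.ones((1, 1, 1), dtype=bool))
    assert out[0, 0, 0] == CSF


def test_classify_noise_free_exact_recovery(seg_truth):
    img = make_synthetic_mri(seg_truth, class_sds=0.0, seed=0)
    intra = seg_truth.labels >= CSF
    model = fit_mog(img.intensities[intra], 3, seed=0)
    model.component_tissue = {0: CSF, 1: GRAY, 2: WHITE}
    out = classify_max_prob(img.intensities, model, intra)
    assert np.array_equal(out[intra], seg_truth.labels[intra])


def test_classify_requires_tissue_mapping():
    model = _toy_model()
    model.component_tissue = None
    with pytest.raises(ValueError, match="component_tissue"):
        classify_max_prob(np.zeros((1, 1, 1)), model, np.ones((1, 1, 1), bool))


# -- full pipeline ----------------------------------------------------------

def test_segment_five_layers_noise_free(seg_truth):
    img = make_synthetic_mri(seg_truth, class_sds=0.0, seed=0)
    seg = segment_five_layers(img)
    for code in range(6):
        assert dice(seg_truth.labels, seg.labels, code) >= 0.99, code


def test_segment_five_layers_snr10(snr10_segmentation):
    truth, seg = snr10_segmentation
    for code in range(6):
        assert dice(truth.labels, seg.labels, code) >= 0.90, code


def test_segment_labels_within_code_range(snr10_segmentation):
    _, seg = snr10_segmentation
    assert set(np.unique(seg.labels)) <= set(range(6))


def test_segment_deterministic(seg_truth):
    img = make_synthetic_mri(seg_truth, seed=3)
    a = segment_five_layers(img)
    b = segment_five_layers(img)
    assert np.array_equal(a.labels, b.labels)


def test_segment_constant_image_raises():
    from nirsim import ScalarVolume
    img = ScalarVolume(np.full((48, 48, 2), 100.0))
    with pytest.raises(ValueError, match="contour"):
        segment_five_layers(img)
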