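"""Sensitivity profiles, separation curves, layer ratios, cross-point."""

import numpy as np
import pytest

from nirsim import (
    LabelVolume,
    SimulationConfig,
    SourceDetectorLayout,
    run_simulation,
)
from nirsim.analysis import (
    CrossPoint,
    SeparationCurve,
    find_cross_separation,
    group_of_visited,
    intensity_vs_separation,
    layer_ratio_curves,
    mean_max_depth,
    run_multiwavelength,
    ssp_accumulate,
    ssp_from_result,
)
from nirsim.mc.engine import SimulationResult
from nirsim.volumes import CSF, GRAY, SCALP, SKULL, WHITE

from conftest import homogeneous_table


def _fake_result(det_index, weight, visited, separations_cm, n_det=None,
                 partial_paths=None, wavelength=800):
    """Hand-built detection records on a trivial layout."""
    n_det = n_det or (max(det_index) + 1 if len(det_index) else 1)
    layout = SourceDetectorLayout(
        source_pos=[0, 0, 0], source_dir=[0, 0, 1],
        det_centers=np.column_stack([np.asarray(separations_cm) * 10.0,
                                     np.zeros(n_det), np.zeros(n_det)]),
        separations_cm=separations_cm)
    det_index = np.asarray(det_index, dtype=np.int32)
    weight = np.asarray(weight, dtype=float)
    cfg = SimulationConfig(volume=None, layout=layout, validate=False,
                           n_photons=max(len(det_index), 1),
                           wavelength_nm=wavelength)
    return SimulationResult(
        config=cfg, det_index=det_index, weight=weight,
        time_ps=np.ones(len(det_index)),
        partial_paths=(partial_paths if partial_paths is not None
                       else np.zeros((len(det_index), 6))),
        visited=np.asarray(visited, dtype=np.uint8),
        absorption=None, ledger={"launched": float(len(det_index))})


def _bit(*codes):
    out = 0
    for c in codes:
        out |= 1 << c
    return np.uint8(out)


# -- sensitivity volumes ----------------------------------------------------

def test_ssp_single_photon_support_is_its_path():
    ptr = np.array([0, 3])
    vox = np.array([4, 9, 14])
    length = np.array([1.0, 0.5, 0.25])
    ssp = ssp_accumulate(np.array([0]), np.array([0.8]), (ptr, vox, length),
                         detector=0, shape=(3, 3, 3))
    flat = ssp.volume.intensities.ravel()
    assert set(np.flatnonzero(flat)) == {4, 9, 14}
    assert flat[4] == pytest.approx(0.8 * 1.0)
    assert ssp.status == "ok"


def test_ssp_normalized_sums_to_one():
    ptr = np.array([0, 2, 4])
    vox = np.array([0, 1, 1, 2])
    length = np.array([1.0, 2.0, 0.5, 0.125])
    ssp = ssp_accumulate(np.array([0, 0]), np.array([0.5, 0.25]),
                         (ptr, vox, length), detector=0, shape=(1, 1, 3),
                         normalize=True)
    assert ssp.volume.intensities.sum() == pytest.approx(1.0, abs=1e-12)


def test_ssp_empty_detector_flagged():
    ssp = ssp_accumulate(np.array([0]), np.array([1.0]),
                         (np.array([0, 1]), np.array([0]), np.array([1.0])),
                         detector=3, shape=(2, 2, 2))
    assert ssp.status == "empty"
    assert not ssp.volume.intensities.any()


def test_ssp_additive_over_disjoint_photon_sets():
    rng = np.random.default_rng(0)
    n = 40
    counts = rng.integers(1, 6, n)
    ptr = np.concatenate([[0], np.cumsum(counts)])
    vox = rng.integers(0, 27, ptr[-1])
    length = rng.random(ptr[-1])
    weight = rng.random(n)
    det = np.zeros(n, dtype=np.int32)
    whole = ssp_accumulate(det, weight, (ptr, vox, length), 0, (3, 3, 3))
    # split photons into two halves by masking weights to zero
    w1, w2 = weight.copy(), weight.copy()
    w1[n // 2:] = 0.0
    w2[: n // 2] = 0.0
    part1 = ssp_accumulate(det, w1, (ptr, vox, length), 0, (3, 3, 3))
    part2 = ssp_accumulate(det, w2, (ptr, vox, length), 0, (3, 3, 3))
    assert np.allclose(part1.volume.intensities + part2.volume.intensities,
                       whole.volume.intensities, atol=1e-12)


def test_ssp_ballistic_is_source_detector_line():
    """Without scattering the SSP support is the straight line of voxels."""
    L = 12
    lv = LabelVolume(np.full((9, 9, L), WHITE, dtype=np.uint8))
    layout = SourceDetectorLayout(
        source_pos=[4.5, 4.5, 0.0], source_dir=[0, 0, 1],
        det_centers=[[4.5, 4.5, float(L)]], det_radius_mm=1.0,
        separations_cm=[0.0])
    cfg = SimulationConfig(volume=lv, layout=layout,
                           table=homogeneous_table(0.01, 0.0, n=1.0),
                           n_photons=3, seed=0, record_paths=True,
                           roulette_enabled=False, validate=False)
    res = run_simulation(cfg)
    ssp = ssp_from_result(res, 0)
    support = np.argwhere(ssp.volume.intensities > 0)
    assert len(support) == L
    assert np.all(support[:, 0] == 4) and np.all(support[:, 1] == 4)


def test_ssp_kernel_accumulation_matches_path_logs(small_head, table_all):
    """Dual route: kernel-side SSP equals the log-based accumulation."""
    from nirsim import surface_layout
    layout = surface_layout(small_head, view="transverse",
                            source_depth_mm=25.0, separations_cm=[1.0, 2.0])
    cfg = SimulationConfig(volume=small_head, layout=layout, table=table_all,
                           n_photons=5000, seed=13, ssp_detectors=(0,),
                           record_paths=True)
    res = run_simulation(cfg)
    from_kernel = res.ssp[0].intensities
    from_logs = ssp_accumulate(res.det_index, res.weight, res.paths, 0,
                               small_head.shape).volume.intensities
    assert np.allclose(from_kernel, from_logs, rtol=1e-5, atol=1e-7)


# -- separation curves ------------------------------------------------------

def test_intensity_curve_keeps_zero_detectors():
    res = _fake_result([0, 0, 2], [0.5, 0.25, 0.125], [0, 0, 0],
                       separations_cm=[1.0, 2.0, 3.0], n_det=3)
    curve = intensity_vs_separation(res)
    assert np.allclose(curve.values, [0.75, 0.0, 0.125])


def test_intensity_doubles_with_photon_count(small_head, table_all):
    from nirsim import surface_layout
    layout = surface_layout(small_head, view="transverse",
                            source_depth_mm=25.0, separations_cm=[1.0, 2.0])
    def total(n):
        cfg = SimulationConfig(volume=small_head, layout=layout,
                               table=table_all, n_photons=n, seed=14)
        return run_simulation(cfg).detected_weight_per_detector()
    t1, t2 = total(20_000), total(40_000)
    # doubling the photon count doubles the intensity within sampling error
    assert t2.sum() == pytest.approx(2.0 * t1.sum(), rel=0.15)


def test_separation_curve_requires_increasing_grid():
    with pytest.raises(ValueError, match="increasing"):
        SeparationCurve(np.array([1.0, 1.0]), np.array([0.0, 0.0]))


# -- layer ratios -----------------------------------------------------------

def test_group_partition_of_visited_masks():
    visited = [_bit(SCALP), _bit(SCALP, SKULL), _bit(SKULL, CSF),
               _bit(SCALP, CSF, GRAY), _bit(WHITE)]
    assert list(group_of_visited(visited)) == [0, 0, 1, 2, 2]


def test_layer_ratios_partition_sums_to_one():
    rng = np.random.default_rng(1)
    n = 500
    det = rng.integers(0, 4, n)
    visited = rng.choice([_bit(SCALP), _bit(SCALP, SKULL, CSF),
                          _bit(SCALP, SKULL, CSF, GRAY)], n)
    res = _fake_result(det, rng.random(n), visited,
                       separations_cm=[1.0, 2.0, 3.0, 4.0], n_det=4)
    curves = layer_ratio_curves(res)
    total = sum(c.values for c in curves.values())
    assert np.allclose(total, 1.0, atol=1e-12)


def test_layer_ratios_all_cortex():
    res = _fake_result([0, 1], [1.0, 1.0], [_bit(SCALP, WHITE)] * 2,
                       separations_cm=[1.0, 2.0], n_det=2)
    curves = layer_ratio_curves(res)
    assert np.allclose(curves["cortex"].values, 1.0)
    assert np.allclose(curves["surface"].values, 0.0)


def test_layer_ratios_zero_weight_flagged_undefined():
    res = _fake_result([0], [1.0], [_bit(SCALP)],
                       separations_cm=[1.0, 2.0], n_det=2)
    curves = layer_ratio_curves(res)
    assert curves["surface"].undefined[1]
    assert np.isnan(curves["surface"].values[1])


def test_layer_ratios_pathlength_variant_partitions():
    pp = np.zeros((3, 6))
    pp[:, SCALP] = [5.0, 1.0, 0.0]
    pp[:, CSF] = [0.0, 1.0, 2.0]
    pp[:, GRAY] = [5.0, 2.0, 0.0]
    res = _fake_result([0, 0, 1], [1.0, 0.5, 2.0],
                       [_bit(SCALP, GRAY), _bit(SCALP, CSF, GRAY), _bit(CSF)],
                       separations_cm=[1.0, 2.0], n_det=2, partial_paths=pp)
    curves = layer_ratio_curves(res, definition="pathlength")
    total = sum(c.values for c in curves.values())
    assert np.allclose(total, 1.0, atol=1e-12)
    assert curves["csf"].values[1] == pytest.approx(1.0)


def test_thick_scalp_shallow_sampling_at_short_separation():
    """A slab with 40 mm of scalp: at 1 cm the surface group dominates."""
    from nirsim import PhantomSpec, make_layered_slab_phantom, slab_layout
    spec = PhantomSpec(kind="layered-slab", grid_shape=(120, 80, 60),
                       scalp_mm=40, skull_mm=5, csf_mm=2, gray_mm=4)
    lv = make_layered_slab_phantom(spec)
    layout = slab_layout(lv, separations_cm=[1.0])
    from nirsim import build_tissue_table
    cfg = SimulationConfig(volume=lv, layout=layout,
                           table=build_tissue_table({800}),
                           n_photons=50_000, seed=15)
    res = run_simulation(cfg)
    curves = layer_ratio_curves(res)
    assert curves["surface"].values[0] > curves["cortex"].values[0]


# -- cross-point ------------------------------------------------------------

def _curves(seps, surface, cortex):
    return (SeparationCurve(np.asarray(seps), np.asarray(surface)),
            SeparationCurve(np.asarray(seps), np.asarray(cortex)))


def test_cross_at_exact_grid_point():
    s, c = _curves([2.0, 3.0, 4.0], [0.6, 0.5, 0.3], [0.2, 0.5, 0.7])
    cp = find_cross_separation(s, c)
    assert cp.separation_cm == pytest.approx(3.0)
    assert cp.status == "ok"


def test_cross_linear_interpolation_midpoint():
    s, c = _curves([3.0, 4.0], [0.6, 0.4], [0.4, 0.6])
    cp = find_cross_separation(s, c)
    assert cp.separation_cm == pytest.approx(3.5)


def test_cross_absent_when_no_crossing():
    s, c = _curves([1.0, 2.0], [0.9, 0.8], [0.1, 0.2])
    cp = find_cross_separation(s, c)
    assert cp.status == "none" and cp.separation_cm is None


def test_cross_multiple_crossings_returns_smallest_flagged():
    s, c = _curves([1, 2, 3, 4], [0.6, 0.4, 0.6, 0.4],
                   [0.4, 0.6, 0.4, 0.6])
    cp = find_cross_separation(s, c)
    assert cp.separation_cm == pytest.approx(1.5)
    assert cp.multiple


def test_cross_symmetric_under_curve_exchange():
    s, c = _curves([3.0, 4.0], [0.7, 0.3], [0.3, 0.7])
    assert (find_cross_separation(s, c).separation_cm
            == find_cross_separation(c, s).separation_cm)


def test_cross_rejects_mismatched_grids():
    s, _ = _curves([1.0, 2.0], [0.5, 0.5], [0.5, 0.5])
    c = SeparationCurve(np.array([1.0, 3.0]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="grid"):
        find_cross_separation(s, c)


def test_cross_skips_undefined_separations():
    s, c = _curves([1, 2, 3], [0.6, np.nan, 0.4], [0.4, np.nan, 0.6])
    cp = find_cross_separation(s, c)
    assert cp.separation_cm == pytest.approx(2.0)  # interpolated across the gap


# -- multi-wavelength -------------------------------------------------------

def test_multiwavelength_identical_props_and_seed_identical_curves(small_head):
    from nirsim import surface_layout
    table = homogeneous_table(0.02, 1.5, g=0.9, n=1.4)  # same at every band
    layout = surface_layout(small_head, view="transverse",
                            source_depth_mm=25.0, separations_cm=[1.0, 2.0])
    base = SimulationConfig(volume=small_head, layout=layout, table=table,
                            n_photons=10_000, seed=16)
    out = run_multiwavelength(base, wavelengths=(800, 800),
                              seeds={800: 3})
    # a single entry per distinct wavelength; rerun manually for the pair
    out2 = run_multiwavelength(base, wavelengths=(800,), seeds={800: 3})
    assert np.array_equal(out[800]["intensity"].values,
                          out2[800]["intensity"].values)


def test_higher_absorption_lowers_intensity_everywhere():
    lv = LabelVolume(np.full((100, 80, 40), WHITE, dtype=np.uint8))
    from nirsim import slab_layout
    layout = slab_layout(lv, separations_cm=[1.0, 2.0, 3.0])
    def run(mu_a):
        cfg = SimulationConfig(volume=lv, layout=layout,
                               table=homogeneous_table(mu_a, 1.5, 0.9, 1.4),
                               n_photons=40_000, seed=17)
        return run_simulation(cfg).detected_weight_per_detector()
    low, high = run(0.01), run(0.05)
    assert np.all(high < low)


def test_longer_wavelength_absorbed_more_on_phantom(small_head, table_all):
    """830 nm is absorbed more strongly than 690 nm in the head model."""
    from nirsim import surface_layout
    layout = surface_layout(small_head, view="transverse",
                            source_depth_mm=25.0,
                            separations_cm=[1.0, 2.0, 3.0])
    base = SimulationConfig(volume=small_head, layout=layout, table=table_all,
                            n_photons=60_000, seed=18)
    out = run_multiwavelength(base, wavelengths=(690, 830),
                              seeds={690: 5, 830: 5})
    t690 = out[690]["intensity"].values.sum()
    t830 = out[830]["intensity"].values.sum()
    assert t830 < t690


def test_multiwavelength_missing_table_entry_raises(small_head):
    from nirsim import surface_layout
    table = homogeneous_table(0.02, 1.5)  # 800 nm only
    layout = surface_layout(small_head, view="transverse",
                            source_depth_mm=25.0, separations_cm=[1.0])
    base = SimulationConfig(volume=small_head, layout=layout, table=table,
                            n_photons=100, seed=0)
    with pytest.raises(KeyError):
        run_multiwavelength(base, wavelengths=(690,))


# -- CSF expansion and penetration depth ------------------------------------

def test_csf_expansion_does_not_reduce_penetration_depth(small_head_spec,
                                                         table_all):
    """Expanding the CSF spaces lets detected light sample deeper tissue."""
    from dataclasses import replace
    from scipy import ndimage
    from nirsim import make_folded_head_phantom, surface_layout

    depths = []
    for factor in (1.0, 2.0):
        lv = make_folded_head_phantom(replace(small_head_spec,
                                              csf_expansion=factor))
        layout = surface_layout(lv, view="transverse", source_depth_mm=25.0,
                                separations_cm=[2.0, 3.0])
        cfg = SimulationConfig(volume=lv, layout=layout, table=table_all,
                               n_photons=60_000, seed=19, record_paths=True)
        res = run_simulation(cfg)
        depth_map = ndimage.distance_transform_edt(lv.labels > 0)
        depths.append(mean_max_depth(res, lv, depth_map))
    assert depths[1] >= depths[0] - 0.5  # within MC error at fixed seed
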