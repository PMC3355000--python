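"""Shared fixtures: small phantoms and the expensive session-scoped runs."""

from __future__ import annotations

import numpy as np
import pytest

from nirsim import (
    LabelVolume,
    PhantomSpec,
    SimulationConfig,
    SourceDetectorLayout,
    build_tissue_table,
    make_folded_head_phantom,
    make_synthetic_mri,
    run_simulation,
)
from nirsim.optics import OpticalProperties, TissueOpticalTable
from nirsim.phantoms import DEFAULT_T1_MEANS


def homogeneous_table(mu_a: float, mu_s: float, g: float = 0.0,
                      n: float = 1.0, n_air: float = 1.0) -> TissueOpticalTable:
    """All five tissues share one set of optical properties (test medium).

    ``mu_s`` is stored in the reduced-scattering slot; pair with
    ``scattering_mode="as-paper"`` to use it directly as the scattering rate.
    """
    entries = {(c, 800): OpticalProperties(mu_a, mu_s, g, n)
               for c in range(1, 6)}
    return TissueOpticalTable(entries, n_air=n_air)


def dice(a: np.ndarray, b: np.ndarray, code: int) -> float:
    A, B = a == code, b == code
    return 2.0 * float((A & B).sum()) / max(float(A.sum() + B.sum()), 1.0)


@pytest.fixture(scope="session")
def table_all():
    return build_tissue_table()


@pytest.fixture(scope="session")
def small_head_spec():
    """Folded half-head small enough for fast segmentation/transport tests."""
    return PhantomSpec(
        kind="folded-head", grid_shape=(96, 96, 40),
        semi_axes_mm=(40.0, 44.0, 60.0), head_top_mm=2.0,
        scalp_mm=3.0, skull_mm=5.0, csf_mm=2.0, gray_mm=5.0,
        n_sulci=4, sulcus_depth_mm=6.0, fissure_depth_mm=30.0,
    )


@pytest.fixture(scope="session")
def small_head(small_head_spec):
    return make_folded_head_phantom(small_head_spec)


@pytest.fixture(scope="session")
def seg_truth(small_head):
    """Four mid-slices of the small head (segmentation ground truth)."""
    return LabelVolume(small_head.labels[:, :, 18:22].copy())


@pytest.fixture(scope="session")
def snr10_segmentation(seg_truth):
    """Five-layer segmentation of an SNR-10 synthetic T1 (per-class sd =
    mean/10), with its ground truth."""
    from nirsim.segmentation import segment_five_layers
    sds = {c: m / 10.0 for c, m in DEFAULT_T1_MEANS.items()}
    img = make_synthetic_mri(seg_truth, class_sds=sds, seed=11)
    return seg_truth, segment_five_layers(img)


@pytest.fixture(scope="session")
def folded_head_full():
    """The bundled folded five-layer head phantom at study dimensions."""
    return make_folded_head_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def folded_run_1e6(folded_head_full):
    """The headline transport run: 1e6 packets at 800 nm, transverse row."""
    from nirsim import surface_layout
    layout = surface_layout(folded_head_full, view="transverse",
                            source_depth_mm=60.0)
    cfg = SimulationConfig(volume=folded_head_full, layout=layout,
                           wavelength_nm=800, n_photons=1_000_000, seed=20)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def diffusion_run():
    """Homogeneous semi-infinite medium (mu_s' = 1, mu_a = 0.01 /mm, index
    matched): ring of 8 detector disks at 20 mm separation."""
    lv = LabelVolume(np.full((160, 160, 80), 5, dtype=np.uint8))
    table = homogeneous_table(mu_a=0.01, mu_s=1.0, g=0.0, n=1.0)
    rho, r = 20.0, 3.0
    ang = np.arange(8) * np.pi / 4
    dets = np.column_stack([80 + rho * np.cos(ang), 80 + rho * np.sin(ang),
                            np.zeros(8)])
    layout = SourceDetectorLayout(
        source_pos=[80.0, 80.0, 0.0], source_dir=[0.0, 0.0, 1.0],
        det_centers=dets, det_radius_mm=r,
        separations_cm=rho / 10 + np.arange(8) * 1e-9,
    )
    cfg = SimulationConfig(volume=lv, layout=layout, table=table,
                           scattering_mode="as-paper", n_photons=400_000,
                           seed=7, gate_ps=1500.0, roulette_enabled=False)
    return run_simulation(cfg), 0.01, 1.0, rho, r
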