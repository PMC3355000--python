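"""Synthetic head phantoms and T1-like image synthesis.

The in-vivo study volume behind the published head model is not available,
so these generators stand in for it in two roles:

* **Transport geometry** — :func:`make_layered_slab_phantom` builds the
  classic five-layer slab, and :func:`make_folded_head_phantom` builds a
  half-head of concentric shells (scalp, skull, CSF, gray matter around a
  white-matter core) with CSF-filled sulcal grooves cut through the cortex
  and a midline interhemispheric fissure.  The fissure and the CSF shell can
  be widened through ``csf_expansion`` to emulate the expanded-CSF (brain
  atrophy) condition.
* **Segmentation input** — :func:`make_synthetic_mri` renders any label
  volume into a T1-like intensity image with per-class Gaussian noise.

All generators are pure functions of (spec, seed): identical inputs yield
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import AIR, CSF, GRAY, LabelVolume, SCALP, SKULL, ScalarVolume, WHITE

#: T1-like per-class intensity means (arbitrary units): CSF darkest among
#: intracranial tissues, then gray, then white; skull dark, scalp bright.
DEFAULT_T1_MEANS = {AIR: 30.0, SCALP: 210.0, SKULL: 90.0, CSF: 45.0,
                    GRAY: 130.0, WHITE: 180.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic five-layer phantom.

    ``kind`` selects ``"layered-slab"`` (layers stacked along the axial axis
    from the illuminated face at slice 0) or ``"folded-head"`` (the upper
    part of concentric ellipsoidal shells; slice 0 is the head top).
    Thicknesses are in mm, measured inward from the outer surface; the
    remainder of the head is white matter.
    """

    kind: str = "folded-head"
    grid_shape: tuple[int, int, int] = (256, 256, 92)
    voxel_size_mm: float = 1.0
    scalp_mm: float = 3.0
    skull_mm: float = 7.0
    csf_mm: float = 2.0
    gray_mm: float = 4.0
    # folded-head only:
    semi_axes_mm: tuple[float, float, float] = (85.0, 105.0, 115.0)
    head_top_mm: float = 2.0        # depth of the apex below slice 0
    n_sulci: int = 8
    sulcus_width_mm: float = 2.0
    sulcus_depth_mm: float = 8.0    # below the inner skull surface
    fissure_width_mm: float = 3.0
    fissure_depth_mm: float = 50.0
    csf_expansion: float = 1.0      # scales CSF shell thickness and fissure width

    def __post_init__(self) -> None:
        if self.kind not in ("layered-slab", "folded-head"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        for name in ("scalp_mm", "skull_mm", "csf_mm", "gray_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.csf_expansion < 1.0:
            raise ValueError("csf_expansion must be >= 1")
        if self.n_sulci < 0 or self.sulcus_width_mm < 0 or self.sulcus_depth_mm < 0:
            raise ValueError("sulcus parameters must be >= 0")

    @property
    def csf_mm_expanded(self) -> float:
        return self.csf_mm * self.csf_expansion


def make_layered_slab_phantom(spec: PhantomSpec) -> LabelVolume:
    """Five-layer slab: scalp, skull, CSF, gray matter stacked from slice 0,
    the rest white matter.  Layer voxel counts satisfy the exact identity
    count = thickness(voxels) x face area.
    """
    if spec.kind != "layered-slab":
        raise ValueError("spec.kind must be 'layered-slab'")
    nx, ny, nz = spec.grid_shape
    h = spec.voxel_size_mm
    bounds_mm = np.cumsum([spec.scalp_mm, spec.skull_mm, spec.csf_mm_expanded,
                           spec.gray_mm])
    if bounds_mm[-1] > nz * h:
        raise ValueError(
            f"layer thicknesses sum to {bounds_mm[-1]} mm, exceeding the "
            f"{nz * h} mm grid depth"
        )
    z_mm = (np.arange(nz) + 0.5) * h  # voxel centres along the slice axis
    labels = np.full((nx, ny, nz), WHITE, dtype=np.uint8)
    layer_codes = (SCALP, SKULL, CSF, GRAY)
    lo = 0.0
    for code, hi in zip(layer_codes, bounds_mm):
        labels[:, :, (z_mm > lo) & (z_mm < hi)] = code
        lo = hi
    return LabelVolume(labels, voxel_size=h)


def _head_depth_mm(mask: np.ndarray, h: float) -> np.ndarray:
    """Euclidean distance (mm) from each in-head voxel to the outer surface.

    Distances are computed against background voxels inside the grid only, so
    the cut plane at the bottom of a half-head grid is not treated as surface.
    """
    return ndimage.distance_transform_edt(mask, sampling=h)


def make_folded_head_phantom(spec: PhantomSpec) -> LabelVolume:
    """Half-head of concentric shells with CSF-filled cortical folds.

    The outer surface is the upper portion of an ellipsoid whose apex sits
    ``head_top_mm`` below slice 0.  Shells are assigned by Euclidean depth
    from the surface; sulci are planar grooves (normal to the x axis) and the
    interhemispheric fissure a midline slot, both filled with CSF and opening
    into the CSF shell.  Deterministic given the spec.
    """
    if spec.kind != "folded-head":
        raise ValueError("spec.kind must be 'folded-head'")
    nx, ny, nz = spec.grid_shape
    h = spec.voxel_size_mm
    ax, ay, az = spec.semi_axes_mm
    t_scalp, t_skull = spec.scalp_mm, spec.skull_mm
    t_csf, t_gray = spec.csf_mm_expanded, spec.gray_mm

    cortical_extent = min(ax, ay, az) - (t_scalp + t_skull + t_csf)
    if spec.sulcus_depth_mm > cortical_extent:
        raise ValueError(
            f"sulcus depth {spec.sulcus_depth_mm} mm exceeds the "
            f"{cortical_extent:.1f} mm cortical (gray+white) extent"
        )

    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    cx, cy = nx * h / 2.0, ny * h / 2.0
    cz = spec.head_top_mm + az  # ellipsoid centre, below the grid bottom
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    mask = (((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2
            + ((Z - cz) / az) ** 2) <= 1.0

    depth = _head_depth_mm(mask, h)
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    b1 = t_scalp
    b2 = b1 + t_skull
    b3 = b2 + t_csf
    b4 = b3 + t_gray
    labels[mask & (depth <= b1)] = SCALP
    labels[mask & (depth > b1) & (depth <= b2)] = SKULL
    labels[mask & (depth > b2) & (depth <= b3)] = CSF
    labels[mask & (depth > b3) & (depth <= b4)] = GRAY
    labels[mask & (depth > b4)] = WHITE

    # CSF-filled folds: grooves through the cortex, opening into the CSF shell.
    def _slot(x_center: float, width: float, bottom: float) -> np.ndarray:
        return (mask & (np.abs(X - x_center) <= width / 2.0)
                & (depth > b2) & (depth <= bottom))

    if spec.n_sulci > 0:
        offsets = np.linspace(-0.55 * ax, 0.55 * ax, spec.n_sulci + 2)[1:-1]
        for dx in offsets:
            if abs(dx) < (spec.fissure_width_mm * spec.csf_expansion):
                continue  # keep sulci clear of the midline fissure
            labels[_slot(cx + dx, spec.sulcus_width_mm,
                         b2 + t_csf + spec.sulcus_depth_mm)] = CSF
    if spec.fissure_width_mm > 0:
        labels[_slot(cx, spec.fissure_width_mm * spec.csf_expansion,
                     b2 + spec.fissure_depth_mm)] = CSF
    return LabelVolume(labels, voxel_size=h)


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "layered-slab":
        return make_layered_slab_phantom(spec)
    return make_folded_head_phantom(spec)


def make_synthetic_mri(
    lv: LabelVolume,
    class_means: dict[int, float] | None = None,
    class_sds: dict[int, float] | float | None = None,
    seed: int = 0,
) -> ScalarVolume:
    """Render a label volume into a T1-like intensity image.

    Each voxel's intensity is drawn from the Gaussian of its tissue code.
    ``class_sds`` may be a per-code dict or one scalar for all codes; 0 gives
    the noise-free piecewise-constant image.  Defaults reproduce a T1-like
    contrast (CSF darkest intracranial class, then gray, then white matter).
    """
    means = dict(DEFAULT_T1_MEANS if class_means is None else class_means)
    if class_sds is None:
        sds = {code: 0.1 * m for code, m in means.items()}
    elif np.isscalar(class_sds):
        sds = {code: float(class_sds) for code in means}
    else:
        sds = dict(class_sds)

    present = np.unique(lv.labels)
    missing = [int(c) for c in present if c not in means or c not in sds]
    if missing:
        raise ValueError(
            f"class mean/sd missing for tissue code(s) {missing} present in the volume"
        )
    mean_lut = np.zeros(int(present.max()) + 1)
    sd_lut = np.zeros_like(mean_lut)
    for code in present:
        mean_lut[code] = means[int(code)]
        sd_lut[code] = sds[int(code)]
        if sd_lut[code] < 0:
            raise ValueError("class standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    img = mean_lut[lv.labels] + sd_lut[lv.labels] * rng.standard_normal(lv.labels.shape)
    return ScalarVolume(img, voxel_size=lv.voxel_size, origin=lv.origin)
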