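"""Source and detector placement on the head surface.

NIRS probes sit on the scalp: one source fibre and a row of detector disks
at increasing source-detector separations (default 1-10 cm in 1 cm steps),
measured *along the surface*.  Two arrangements mirror the transverse and
sagittal probe rows of the study geometry:

* :func:`surface_layout` walks the head-surface contour of one image plane
  (an axial slice for the transverse row, the midline plane for the
  sagittal row) and places detectors at the requested arc lengths from the
  source;
* :func:`slab_layout` is the flat-face equivalent for slab phantoms.

Detector disks are flush with the surface (default radius 1.5 mm); any exit
within the disk, at any angle, is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import LabelVolume

DEFAULT_SEPARATIONS_CM = tuple(float(s) for s in range(1, 11))
DEFAULT_DETECTOR_RADIUS_MM = 1.5


@dataclass
class SourceDetectorLayout:
    """Source position/direction and detector disk centres, all in mm."""

    source_pos: np.ndarray
    source_dir: np.ndarray
    det_centers: np.ndarray              # (ndet, 3)
    det_radius_mm: float = DEFAULT_DETECTOR_RADIUS_MM
    separations_cm: np.ndarray | None = None  # per detector, for reporting

    def __post_init__(self) -> None:
        self.source_pos = np.asarray(self.source_pos, dtype=np.float64)
        d = np.asarray(self.source_dir, dtype=np.float64)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("source_dir must be non-zero")
        self.source_dir = d / norm
        self.det_centers = np.atleast_2d(
            np.asarray(self.det_centers, dtype=np.float64))
        if self.det_radius_mm <= 0:
            raise ValueError("det_radius_mm must be > 0")
        if self.separations_cm is not None:
            self.separations_cm = np.asarray(self.separations_cm, dtype=np.float64)
            if len(self.separations_cm) != len(self.det_centers):
                raise ValueError("one separation per detector required")

    @property
    def n_detectors(self) -> int:
        return len(self.det_centers)


def slab_layout(
    lv: LabelVolume,
    separations_cm=DEFAULT_SEPARATIONS_CM,
    det_radius_mm: float = DEFAULT_DETECTOR_RADIUS_MM,
) -> SourceDetectorLayout:
    """Source at the centre of the illuminated face (slice 0), detectors in a
    row along +x on the same face."""
    nx, ny, nz = lv.shape
    hx, hy, hz = lv.voxel_size
    seps_mm = np.asarray(separations_cm, dtype=np.float64) * 10.0
    src = np.array([nx * hx / 2.0, ny * hy / 2.0, 0.0])
    if seps_mm.size and src[0] + seps_mm.max() >= nx * hx:
        raise ValueError(
            f"largest separation {seps_mm.max()} mm falls off the "
            f"{nx * hx} mm wide face"
        )
    centers = np.column_stack([
        src[0] + seps_mm,
        np.full_like(seps_mm, src[1]),
        np.zeros_like(seps_mm),
    ])
    return SourceDetectorLayout(
        source_pos=src,
        source_dir=np.array([0.0, 0.0, 1.0]),
        det_centers=centers,
        det_radius_mm=det_radius_mm,
        separations_cm=np.asarray(separations_cm, dtype=np.float64),
    )


def _plane_contour(mask2d: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of a 2-D head mask, in index coordinates."""
    contours = measure.find_contours(mask2d.astype(float), 0.5)
    if not contours:
        raise ValueError("no head surface found in the requested plane")
    return max(contours, key=len)


def surface_layout(
    lv: LabelVolume,
    view: str = "transverse",
    source_depth_mm: float = 60.0,
    separations_cm=DEFAULT_SEPARATIONS_CM,
    det_radius_mm: float = DEFAULT_DETECTOR_RADIUS_MM,
    walk_sign: int = +1,
) -> SourceDetectorLayout:
    """Place the source and a detector row along the head-surface contour.

    ``view="transverse"`` works in the axial slice ``source_depth_mm`` below
    the head top, with the source at the anterior-most (minimum y) surface
    point — the frontal surface at the stated depth from the head top.
    ``view="sagittal"`` works in the midline (x = centre) plane, with the
    source at the same frontal point.  Detectors sit at the requested arc
    lengths from the source, walking the contour in the direction selected
    by ``walk_sign``.
    """
    if view not in ("transverse", "sagittal"):
        raise ValueError(f"view must be 'transverse' or 'sagittal', got {view!r}")
    hx, hy, hz = lv.voxel_size
    head = lv.labels > 0
    seps_mm = np.asarray(separations_cm, dtype=np.float64) * 10.0

    z_idx = int(source_depth_mm / hz)
    if not 0 <= z_idx < lv.shape[2]:
        raise ValueError(f"source depth {source_depth_mm} mm outside the grid")
    if view == "transverse":
        mask2d = head[:, :, z_idx]
        contour = _plane_contour(mask2d)  # (x_idx, y_idx)
        pts = np.column_stack([(contour[:, 0] + 0.5) * hx,
                               (contour[:, 1] + 0.5) * hy])
        fixed = (source_depth_mm // hz + 0.5) * hz
        embed = lambda p: np.array([p[0], p[1], fixed])
        anchor = pts[np.argmin(pts[:, 1])]           # anterior-most point
    else:
        x_idx = lv.shape[0] // 2
        mask2d = head[x_idx, :, :]
        contour = _plane_contour(mask2d)  # (y_idx, z_idx)
        pts = np.column_stack([(contour[:, 0] + 0.5) * hy,
                               (contour[:, 1] + 0.5) * hz])
        fixed = (x_idx + 0.5) * hx
        embed = lambda p: np.array([fixed, p[0], p[1]])
        # frontal point at the source depth: minimum y among points near it
        near = np.abs(pts[:, 1] - source_depth_mm) <= max(2.0, 2.0 * hz)
        if not near.any():
            raise ValueError("no surface point near the requested source depth")
        cand = np.where(near)[0]
        anchor = pts[cand[np.argmin(pts[cand, 0])]]

    i_src = int(np.argmin(np.sum((pts - anchor) ** 2, axis=1)))
    # cumulative arc length walking from the source
    order = np.roll(np.arange(len(pts)), -i_src)[:: 1 if walk_sign > 0 else -1]
    walk = pts[order]
    if walk_sign < 0:
        walk = np.roll(walk, 1, axis=0)
    steps = np.linalg.norm(np.diff(walk, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    if seps_mm.size and seps_mm.max() > arc[-1]:
        raise ValueError(
            f"separation {seps_mm.max()} mm exceeds the {arc[-1]:.0f} mm contour"
        )
    centroid = pts.mean(axis=0)

    def _surface_point(arclen: float) -> tuple[np.ndarray, np.ndarray]:
        j = int(np.searchsorted(arc, arclen))
        j = min(max(j, 1), len(arc) - 1)
        frac = (arclen - arc[j - 1]) / max(arc[j] - arc[j - 1], 1e-12)
        p = walk[j - 1] + frac * (walk[j] - walk[j - 1])
        inward = centroid - p
        inward /= np.linalg.norm(inward)
        return p, inward

    src2d, inward2d = _surface_point(0.0)
    src = embed(src2d)
    sdir = embed(inward2d) - embed([0.0, 0.0])
    sdir /= np.linalg.norm(sdir)
    src = _snap_to_surface(lv, src, sdir)
    centers = np.array([embed(_surface_point(s)[0]) for s in seps_mm]) \
        if seps_mm.size else np.zeros((0, 3))
    return SourceDetectorLayout(
        source_pos=src,
        source_dir=sdir,
        det_centers=centers,
        det_radius_mm=det_radius_mm,
        separations_cm=np.asarray(separations_cm, dtype=np.float64),
    )


def _snap_to_surface(lv: LabelVolume, pos: np.ndarray, inward: np.ndarray,
                     max_mm: float = 4.0) -> np.ndarray:
    """Walk ``pos`` along ``inward`` until just inside the first tissue voxel."""
    h = min(lv.voxel_size)
    step = 0.1 * h
    p = pos.astype(np.float64).copy()
    for _ in range(int(max_mm / step)):
        idx = np.floor(p / np.asarray(lv.voxel_size)).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.array(lv.shape)):
            if lv.labels[tuple(idx)] > 0:
                return p
        p += inward * step
    raise ValueError("source direction never enters tissue (not on the surface?)")


def _boundary_mask(lv: LabelVolume) -> np.ndarray:
    """Tissue voxels with an air (or grid-exterior) face neighbour."""
    head = lv.labels > 0
    interior = ndimage.binary_erosion(head, border_value=0)
    return head & ~interior


def validate_layout(lv: LabelVolume, layout: SourceDetectorLayout) -> None:
    """Check that the source and every detector sit on the air-tissue surface.

    Raises ``ValueError`` naming the offending element.  Positions are
    accepted when their nearest voxel is within ~1.5 voxels of a tissue
    voxel that touches air (the grid exterior counts as air).
    """
    boundary = _boundary_mask(lv)
    if not boundary.any():
        raise ValueError("volume has no air-tissue surface")
    bidx = np.argwhere(boundary)
    h = np.asarray(lv.voxel_size)
    bpos = (bidx + 0.5) * h

    def _near_surface(p: np.ndarray) -> bool:
        d2 = np.sum((bpos - p) ** 2, axis=1)
        return bool(np.min(d2) <= (1.5 * h.max()) ** 2)

    if not _near_surface(layout.source_pos):
        raise ValueError(f"source at {layout.source_pos} is not on the surface")
    probe = layout.source_pos + layout.source_dir * 1.5 * h.min()
    idx = np.floor(probe / h).astype(int)
    if not (np.all(idx >= 0) and np.all(idx < np.array(lv.shape))
            and lv.labels[tuple(idx)] > 0):
        raise ValueError("source direction does not point into tissue")
    for i, c in enumerate(layout.det_centers):
        if not _near_surface(c):
            raise ValueError(f"detector {i} at {c} is not on the surface")
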