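"""Voxel volume containers and file I/O.

Two containers cover every grid used in the pipeline: :class:`LabelVolume`
holds integer tissue codes (the head model) and :class:`ScalarVolume` holds
real-valued intensities (T1-like images, absorption maps, sensitivity
profiles).  Both carry physical voxel size and origin so downstream code can
work in millimetres.

Conventions
-----------
* Tissue codes: 0 = air/background, 1 = scalp, 2 = skull, 3 = CSF,
  4 = gray matter, 5 = white matter.
* Voxel indices are 0-based; voxel ``i`` spans the half-open physical
  interval ``[origin + i*h, origin + (i+1)*h)`` mm along each axis.
* The third array axis is the axial (slice) axis; slice 0 is the head top.
* Grid exterior is treated as air by every consumer of these containers.

Volumes are saved either as NIfTI (labels as uint8, intensities as float32)
or as a raw binary grid next to a plain-text JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Canonical tissue codes of the five-layer head model.
AIR, SCALP, SKULL, CSF, GRAY, WHITE = 0, 1, 2, 3, 4, 5

TISSUE_NAMES = {
    AIR: "air",
    SCALP: "scalp",
    SKULL: "skull",
    CSF: "csf",
    GRAY: "gray_matter",
    WHITE: "white_matter",
}
TISSUE_CODES = {name: code for code, name in TISSUE_NAMES.items()}

#: Number of distinct codes (air + five tissues).
N_CODES = 6


def _as_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(vs)) or np.any(vs <= 0):
        raise ValueError(f"voxel_size must be strictly positive, got {vs}")
    return (float(vs[0]), float(vs[1]), float(vs[2]))


@dataclass
class LabelVolume:
    """3-D grid of tissue codes with physical voxel geometry.

    Parameters
    ----------
    labels
        ``(nx, ny, nz)`` integer array of codes in ``{0..5}``.
    voxel_size
        Physical edge length of a voxel in mm, scalar or per-axis triple.
    origin
        Physical position (mm) of the corner of voxel ``(0, 0, 0)``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, np.round(labels)):
                raise ValueError("labels must be integer tissue codes")
            labels = labels.astype(np.uint8)
        bad = np.setdiff1d(np.unique(labels), np.arange(N_CODES))
        if bad.size:
            raise ValueError(
                f"unknown tissue code(s) {bad.tolist()}; valid codes are 0..5"
            )
        self.labels = np.ascontiguousarray(labels.astype(np.uint8))
        self.voxel_size = _as_voxel_size(self.voxel_size)
        self.origin = tuple(float(x) for x in np.asarray(self.origin, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis in mm."""
        return tuple(n * h for n, h in zip(self.labels.shape, self.voxel_size))

    def tissue_counts(self) -> dict[int, int]:
        """Voxel count per tissue code (codes absent from the grid map to 0)."""
        counts = np.bincount(self.labels.ravel(), minlength=N_CODES)
        return {code: int(counts[code]) for code in range(N_CODES)}

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and self.voxel_size == other.voxel_size
            and self.origin == other.origin
        )


@dataclass
class ScalarVolume:
    """3-D grid of real values (image intensities, deposited weight, ...)."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"intensities must be 3-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        self.intensities = np.ascontiguousarray(arr)
        self.voxel_size = _as_voxel_size(self.voxel_size)
        self.origin = tuple(float(x) for x in np.asarray(self.origin, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


Volume = LabelVolume | ScalarVolume


def _affine(voxel_size, origin) -> np.ndarray:
    aff = np.diag([*voxel_size, 1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume to disk.

    ``*.nii``/``*.nii.gz`` go through nibabel (labels as uint8, intensities
    as float32).  Any other suffix writes a raw little-endian binary grid plus
    a ``<path>.json`` sidecar holding dims, voxel size, origin and dtype.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        if isinstance(volume, LabelVolume):
            data = volume.labels.astype(np.uint8)
        else:
            data = volume.intensities.astype(np.float32)
        img = nib.Nifti1Image(data, _affine(volume.voxel_size, volume.origin))
        img.header.set_zooms(volume.voxel_size)
        nib.save(img, str(path))
        return path
    # raw + sidecar
    if isinstance(volume, LabelVolume):
        data, dtype, kind = volume.labels.astype("<u1"), "<u1", "labels"
    else:
        data, dtype, kind = volume.intensities.astype("<f4"), "<f4", "intensities"
    path.write_bytes(data.tobytes(order="C"))
    sidecar = {
        "kind": kind,
        "shape": list(data.shape),
        "voxel_size_mm": list(volume.voxel_size),
        "origin_mm": list(volume.origin),
        "dtype": dtype,
        "order": "C",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_volume(path: str | Path) -> Volume:
    """Load a volume written by :func:`save_volume`.

    Round trip preserves grid, voxel size and origin bit-exactly for integer
    labels.  Label files containing codes outside ``{0..5}`` are rejected.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(x) for x in img.affine[:3, 3])
        if np.issubdtype(data.dtype, np.integer):
            return LabelVolume(data, voxel_size, origin)
        return ScalarVolume(data.astype(np.float64), voxel_size, origin)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path} (raw volumes need dims and voxel size)"
        )
    meta = json.loads(sidecar_path.read_text())
    for key in ("shape", "voxel_size_mm", "dtype"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} lacks required key {key!r}")
    data = np.frombuffer(path.read_bytes(), dtype=meta["dtype"]).reshape(meta["shape"])
    origin = tuple(meta.get("origin_mm", (0.0, 0.0, 0.0)))
    if meta.get("kind") == "labels":
        return LabelVolume(data.copy(), tuple(meta["voxel_size_mm"]), origin)
    return ScalarVolume(
        data.astype(np.float64), tuple(meta["voxel_size_mm"]), origin
    )
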