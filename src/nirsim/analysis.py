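"""NIRS-design outputs: sensitivity profiles, separation curves, cross-point.

From the detection records and traversal logs of a transport run this
module computes the quantities a probe designer reads off:

* the **spatial sensitivity profile** (SSP) — per-voxel accumulated
  traversal weight of the *detected* photons of one detector: the "banana"
  linking source and detector;
* **intensity versus separation** — total detected weight per detector,
  which falls monotonically with source-detector distance;
* **layer-ratio curves** — the detected weight partitioned by the deepest
  tissue layer each photon visited (surface = scalp/skull only, CSF, cortex
  = gray or white matter); the three fractions sum to 1 at each separation;
* the **cross-point** — the separation where the cortex fraction overtakes
  the surface fraction, the natural lower bound for the optimal
  source-detector separation of a NIRS probe.

A per-layer partial-pathlength variant of the ratio curves is available via
``definition="pathlength"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import SourceDetectorLayout
from .mc.engine import SimulationConfig, SimulationResult, run_simulation
from .volumes import CSF, GRAY, LabelVolume, SCALP, SKULL, ScalarVolume, WHITE

__all__ = [
    "CrossPoint",
    "SeparationCurve",
    "SensitivityVolume",
    "find_cross_separation",
    "intensity_vs_separation",
    "layer_ratio_curves",
    "mean_max_depth",
    "run_multiwavelength",
    "ssp_accumulate",
    "ssp_from_result",
]

_SURFACE_BITS = (1 << SCALP) | (1 << SKULL)
_CSF_BIT = 1 << CSF
_CORTEX_BITS = (1 << GRAY) | (1 << WHITE)

GROUPS = ("surface", "csf", "cortex")


def group_of_visited(visited: np.ndarray) -> np.ndarray:
    """Deepest-layer-visited group index (0 surface, 1 CSF, 2 cortex)."""
    visited = np.asarray(visited)
    out = np.zeros(visited.shape, dtype=np.int8)
    out[(visited & _CSF_BIT) > 0] = 1
    out[(visited & _CORTEX_BITS) > 0] = 2
    return out


@dataclass
class SensitivityVolume:
    """Per-voxel accumulated detected-photon traversal weight (one detector)."""

    volume: ScalarVolume
    detector: int
    normalized: bool = False
    status: str = "ok"  # "empty" when the detector saw no photons

    def normalize(self) -> "SensitivityVolume":
        """Unit-sum variant (per-detector); empty volumes stay empty."""
        total = float(self.volume.intensities.sum())
        if total == 0:
            return replace(self, normalized=True, status="empty")
        vol = ScalarVolume(self.volume.intensities / total,
                           voxel_size=self.volume.voxel_size,
                           origin=self.volume.origin)
        return SensitivityVolume(vol, self.detector, True, self.status)


def ssp_accumulate(
    det_index: np.ndarray,
    weight: np.ndarray,
    paths: tuple[np.ndarray, np.ndarray, np.ndarray],
    detector: int,
    shape: tuple[int, int, int],
    voxel_size=(1.0, 1.0, 1.0),
    normalize: bool = False,
) -> SensitivityVolume:
    """Accumulate detected-photon traversal logs into a sensitivity volume.

    ``paths`` is the CSR traversal log ``(ptr, voxel_flat, length_mm)`` over
    detection records; each detected photon contributes its per-voxel path
    length times its exit weight.  A detector with no detections yields an
    empty volume flagged ``status="empty"``.
    """
    ptr, vox, length = paths
    out = np.zeros(int(np.prod(shape)))
    sel = np.flatnonzero(np.asarray(det_index) == detector)
    for i in sel:
        lo, hi = int(ptr[i]), int(ptr[i + 1])
        np.add.at(out, vox[lo:hi], weight[i] * length[lo:hi])
    vol = ScalarVolume(out.reshape(shape), voxel_size=voxel_size)
    ssp = SensitivityVolume(vol, detector,
                            status="ok" if sel.size else "empty")
    return ssp.normalize() if normalize else ssp


def ssp_from_result(result: SimulationResult, detector: int,
                    normalize: bool = False) -> SensitivityVolume:
    """Sensitivity volume of one detector from a run.

    Uses the kernel-side accumulation when the detector was listed in
    ``ssp_detectors``, else the recorded traversal logs.
    """
    if detector in result.ssp:
        ssp = SensitivityVolume(result.ssp[detector], detector)
        total = float(ssp.volume.intensities.sum())
        ssp.status = "ok" if total > 0 else "empty"
        return ssp.normalize() if normalize else ssp
    if result.paths is None:
        raise ValueError(
            f"detector {detector} was not SSP-accumulated and no traversal "
            "logs were recorded (set record_paths=True or ssp_detectors)"
        )
    lv = result.config.volume
    return ssp_accumulate(result.det_index, result.weight, result.paths,
                          detector, lv.shape, lv.voxel_size, normalize)


@dataclass
class SeparationCurve:
    """Values on a strictly increasing source-detector separation grid (cm)."""

    separations_cm: np.ndarray
    values: np.ndarray
    wavelength_nm: int | None = None
    label: str = ""
    undefined: np.ndarray | None = None  # mask of separations with no signal

    def __post_init__(self) -> None:
        self.separations_cm = np.asarray(self.separations_cm, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(np.diff(self.separations_cm) <= 0):
            raise ValueError("separations must be strictly increasing")
        if len(self.values) != len(self.separations_cm):
            raise ValueError("one value per separation required")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "separation_cm": self.separations_cm,
            "value": self.values,
            "wavelength_nm": self.wavelength_nm,
            "group": self.label,
        })


def _order_by_separation(layout: SourceDetectorLayout):
    if layout.separations_cm is None:
        raise ValueError("layout carries no separations")
    order = np.argsort(layout.separations_cm)
    return order, layout.separations_cm[order]


def intensity_vs_separation(
    result: SimulationResult,
    layout: SourceDetectorLayout | None = None,
    log10: bool = False,
) -> SeparationCurve:
    """Total detected weight per detector, ordered by separation.

    Detectors without detections keep a 0 entry (``-inf`` under ``log10``).
    """
    layout = layout or result.config.layout
    order, seps = _order_by_separation(layout)
    totals = result.detected_weight_per_detector()[order]
    values = np.log10(totals, out=np.full_like(totals, -np.inf),
                      where=totals > 0) if log10 else totals
    return SeparationCurve(seps, values,
                           wavelength_nm=result.config.wavelength_nm,
                           label="intensity_log10" if log10 else "intensity")


def layer_ratio_curves(
    result: SimulationResult,
    layout: SourceDetectorLayout | None = None,
    definition: str = "deepest-layer",
) -> dict[str, SeparationCurve]:
    """Fraction of detected weight per layer group versus separation.

    ``definition="deepest-layer"`` (default) partitions each photon's whole
    weight by the deepest layer it visited: *surface* photons saw only
    scalp/skull, *csf* photons reached the CSF but not the brain, *cortex*
    photons entered gray or white matter.  The three fractions sum to 1.
    ``definition="pathlength"`` instead splits each photon's weight by the
    fraction of its path length spent in each layer group.  Separations
    with zero detected weight are flagged undefined (NaN).
    """
    layout = layout or result.config.layout
    order, seps = _order_by_separation(layout)
    ndet = layout.n_detectors
    group_w = np.zeros((3, ndet))
    if definition == "deepest-layer":
        groups = group_of_visited(result.visited)
        for gi in range(3):
            sel = groups == gi
            np.add.at(group_w[gi], result.det_index[sel], result.weight[sel])
    elif definition == "pathlength":
        pp = result.partial_paths
        total_path = pp[:, 1:].sum(axis=1)
        total_path[total_path == 0] = np.inf
        shares = np.stack([
            (pp[:, SCALP] + pp[:, SKULL]) / total_path,
            pp[:, CSF] / total_path,
            (pp[:, GRAY] + pp[:, WHITE]) / total_path,
        ])
        for gi in range(3):
            np.add.at(group_w[gi], result.det_index,
                      result.weight * shares[gi])
    else:
        raise ValueError(f"unknown ratio definition {definition!r}")
    totals = group_w.sum(axis=0)
    undefined = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals > 0, group_w / totals, np.nan)
    return {
        name: SeparationCurve(
            seps, fractions[gi][order],
            wavelength_nm=result.config.wavelength_nm,
            label=name, undefined=undefined[order],
        )
        for gi, name in enumerate(GROUPS)
    }


@dataclass
class CrossPoint:
    """Crossing of the surface and cortex ratio curves."""

    separation_cm: float | None
    status: str          # "ok" | "none"
    multiple: bool = False


def find_cross_separation(
    surface_curve: SeparationCurve, cortex_curve: SeparationCurve
) -> CrossPoint:
    """Separation where (cortex - surface) changes sign.

    Linear interpolation between adjacent grid points; with several
    crossings the smallest is returned and flagged.  Undefined (NaN)
    separations are skipped.  Returns status ``"none"`` without a crossing.
    """
    if not np.array_equal(surface_curve.separations_cm,
                          cortex_curve.separations_cm):
        raise ValueError("curves are on different separation grids")
    seps = surface_curve.separations_cm
    diff = cortex_curve.values - surface_curve.values
    ok = np.isfinite(diff)
    crossings: list[float] = []
    prev = None  # last finite (sep, diff)
    for s, d, good in zip(seps, diff, ok):
        if not good:
            continue
        if d == 0:
            crossings.append(float(s))
        elif prev is not None and prev[1] != 0 and np.sign(d) != np.sign(prev[1]):
            s0, d0 = prev
            crossings.append(float(s0 + (s - s0) * (-d0) / (d - d0)))
        prev = (float(s), float(d))
    if not crossings:
        return CrossPoint(None, "none")
    crossings = sorted(set(crossings))
    return CrossPoint(crossings[0], "ok", multiple=len(crossings) > 1)


def run_multiwavelength(
    base: SimulationConfig,
    wavelengths=(690, 780, 830),
    seeds: dict[int, int] | None = None,
) -> dict[int, dict]:
    """Run the same geometry at several wavelengths.

    Per-wavelength seeds are derived from the master seed unless given
    explicitly.  Returns, per wavelength, the run result plus intensity and
    layer-ratio curves.
    """
    from dataclasses import replace as _replace
    table = base.table
    if table is not None:
        for wl in wavelengths:
            table.get(1, wl)  # raises if the wavelength is missing
    out: dict[int, dict] = {}
    for wl in wavelengths:
        if seeds is not None and wl in seeds:
            seed = seeds[wl]
        else:
            seed = int(np.random.SeedSequence((base.seed, wl))
                       .generate_state(1)[0] % (2 ** 31))
        cfg = _replace(base, wavelength_nm=int(wl), seed=seed)
        res = run_simulation(cfg)
        out[int(wl)] = {
            "result": res,
            "intensity": intensity_vs_separation(res),
            "ratios": layer_ratio_curves(res),
        }
    return out


def mean_max_depth(result: SimulationResult, lv: LabelVolume,
                   depth_mm: np.ndarray) -> float:
    """Weighted mean, over detected photons, of the deepest voxel visited.

    ``depth_mm`` is a per-voxel depth-below-surface map (same grid as
    ``lv``); requires traversal logs (``record_paths=True``).
    """
    if result.paths is None:
        raise ValueError("traversal logs were not recorded")
    ptr, vox, _ = result.paths
    flat = depth_mm.ravel()
    w_sum = 0.0
    acc = 0.0
    for i in range(result.n_detected):
        lo, hi = int(ptr[i]), int(ptr[i + 1])
        if hi > lo:
            acc += result.weight[i] * float(flat[vox[lo:hi]].max())
            w_sum += result.weight[i]
    if w_sum == 0:
        return float("nan")
    return acc / w_sum
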