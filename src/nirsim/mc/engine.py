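"""Simulation driver and packet-level operations of the transport engine.

:func:`run_simulation` launches N photon packets at the source, advances
them with the JIT kernel and returns detection records, the deposited-weight
(absorption) volume, optional time-binned fluence and per-detector
sensitivity volumes, and a conservation ledger that closes to float
precision.  The scalar operations the engine is built from (step sampling,
Henyey-Greenstein scattering, fractional absorption, Fresnel/Snell surface
interaction, Russian roulette) are also exposed directly for study and
testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..layout import SourceDetectorLayout, validate_layout
from ..optics import TissueOpticalTable, build_tissue_table
from ..volumes import LabelVolume, ScalarVolume
from . import kernel as _k
from .kernel import C_MM_PS

__all__ = [
    "C_MM_PS",
    "PhotonPacket",
    "SimulationConfig",
    "SimulationResult",
    "absorb",
    "advance_through_voxels",
    "fresnel_reflectance",
    "hg_cos_theta",
    "roulette",
    "run_simulation",
    "sample_scatter",
    "sample_step",
    "surface_interaction",
]


# --------------------------------------------------------------------------
# scalar operations
# --------------------------------------------------------------------------

def sample_step(xi: float, mu_t: float) -> float:
    """Free-path sample ``s = -ln(1 - xi) / mu_t`` from the exponential law."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0")
    if not 0.0 <= xi < 1.0:
        raise ValueError("xi must lie in [0, 1)")
    return -math.log(1.0 - xi) / mu_t


def hg_cos_theta(xi, g_hg: float):
    """Inverse-CDF Henyey-Greenstein sample of cos(theta); vectorized over xi."""
    if not -1.0 < g_hg < 1.0:
        raise ValueError("g must lie in (-1, 1)")
    xi = np.asarray(xi, dtype=np.float64)
    if abs(g_hg) < 1e-12:
        out = 2.0 * xi - 1.0
    else:
        tmp = (1.0 - g_hg * g_hg) / (1.0 - g_hg + 2.0 * g_hg * xi)
        out = np.clip((1.0 + g_hg * g_hg - tmp * tmp) / (2.0 * g_hg), -1.0, 1.0)
    return out if out.ndim else float(out)


def sample_scatter(xi_theta: float, xi_psi: float, g_hg: float,
                   direction=None):
    """Sample a scattering deflection ``(theta, psi)``.

    ``cos(theta)`` follows the Henyey-Greenstein inverse CDF (uniform on
    [-1, 1] for g = 0), ``psi = 2*pi*xi`` is isotropic.  When ``direction``
    is given, the rotated unit direction is returned as third element.
    """
    ct = hg_cos_theta(xi_theta, g_hg)
    theta = math.acos(ct)
    psi = 2.0 * math.pi * xi_psi
    if direction is None:
        return theta, psi
    ux, uy, uz = np.asarray(direction, dtype=np.float64)
    new_dir = np.array(_k._rotate_direction(ux, uy, uz, ct, psi))
    return theta, psi, new_dir


def absorb(weight: float, mu_a: float, mu_t: float) -> tuple[float, float]:
    """Fractional absorption at an interaction: returns ``(w_new, dw)`` with
    ``dw = w * mu_a / mu_t`` deposited locally."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0 at an interaction site")
    dw = weight * mu_a / mu_t
    return weight - dw, dw


def fresnel_reflectance(cos_i: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel reflectance; 1.0 beyond the critical angle."""
    if not 0.0 <= cos_i <= 1.0:
        raise ValueError("cos_i must lie in [0, 1]")
    return _k._fresnel_unpolarized(cos_i, n_in, n_out)[0]


def surface_interaction(direction, normal, n_in: float, n_out: float,
                        xi: float):
    """Boundary interaction of an outbound packet.

    ``normal`` is the outward unit surface normal.  Beyond the critical
    angle the packet reflects deterministically; otherwise it reflects with
    probability equal to the unpolarized Fresnel reflectance and exits with
    the Snell-refracted direction (full current weight — binary survival)
    otherwise.  Returns ``(new_direction, exited)``.
    """
    d = np.asarray(direction, dtype=np.float64)
    n = np.asarray(normal, dtype=np.float64)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("surface normal must be unit length")
    cos_i = float(np.dot(d, n))
    if cos_i <= 0:
        raise ValueError("packet is not outbound through this surface")
    refl, cos_t = _k._fresnel_unpolarized(cos_i, n_in, n_out)
    if refl >= 1.0 or xi < refl:
        return d - 2.0 * cos_i * n, False
    eta = n_in / n_out
    t = eta * d + (cos_t - eta * cos_i) * n
    return t / np.linalg.norm(t), True


def roulette(weight: float, threshold: float, survive_prob: float,
             xi: float) -> tuple[float, bool]:
    """Unbiased Russian-roulette termination.

    Below ``threshold`` the packet survives with probability
    ``survive_prob`` (weight boosted by ``1/survive_prob``) or terminates.
    Returns ``(weight, alive)``.
    """
    if not 0.0 < survive_prob <= 1.0:
        raise ValueError("survive_prob must lie in (0, 1]")
    if weight >= threshold:
        return weight, True
    if xi < survive_prob:
        return weight / survive_prob, True
    return 0.0, False


# --------------------------------------------------------------------------
# packet-level voxel marching (reference implementation for small volumes)
# --------------------------------------------------------------------------

@dataclass
class PhotonPacket:
    """Photon-packet state: continuous position (mm), unit direction, weight,
    elapsed time (ps), visited-layer bitmask and per-tissue partial paths."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    elapsed_ps: float = 0.0
    visited_mask: int = 0
    partial_path: np.ndarray = field(default_factory=lambda: np.zeros(6))
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).copy()
        d = np.asarray(self.direction, dtype=np.float64)
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        self.direction = d / norm
        self.partial_path = np.asarray(self.partial_path, dtype=np.float64).copy()


def advance_through_voxels(
    packet: PhotonPacket,
    lv: LabelVolume,
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    n_refr: np.ndarray,
    budget: float,
) -> tuple[PhotonPacket, str]:
    """March a packet until the optical-depth budget is spent or air is hit.

    The ray is traversed voxel by voxel with exact axis-crossing distances;
    each scattering voxel consumes ``mu_t * s`` from the budget, clear
    (``mu_s = 0``) voxels attenuate the weight continuously without
    consuming budget.  Returns the updated packet and ``"interaction"`` or
    ``"surface-hit"`` (packet stopped exactly on the boundary).
    """
    if not packet.alive:
        raise ValueError("packet is not alive")
    pos = packet.position
    d = packet.direction
    h = np.asarray(lv.voxel_size)
    shape = np.array(lv.shape)
    inv_c = 1.0 / C_MM_PS
    while True:
        idx = np.floor(pos / h).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape) or lv.labels[tuple(idx)] == 0:
            raise ValueError("packet is outside tissue")
        lbl = int(lv.labels[tuple(idx)])
        mut = mu_a[lbl] + mu_s[lbl]
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = np.where(
                d > 0, ((idx + 1) * h - pos) / d,
                np.where(d < 0, (idx * h - pos) / d, np.inf),
            )
        kaxis = int(np.argmin(tb))
        dbound = max(float(tb[kaxis]), 0.0)
        if mu_s[lbl] > 0 and mut * dbound >= budget:
            s = budget / mut
            pos += d * s
            packet.elapsed_ps += s * n_refr[lbl] * inv_c
            packet.partial_path[lbl] += s
            packet.visited_mask |= 1 << lbl
            packet.position = pos
            return packet, "interaction"
        s = dbound
        if mu_s[lbl] > 0:
            budget -= mut * s
        elif mu_a[lbl] > 0:
            packet.weight *= math.exp(-mu_a[lbl] * s)
        pos += d * s
        packet.elapsed_ps += s * n_refr[lbl] * inv_c
        packet.partial_path[lbl] += s
        packet.visited_mask |= 1 << lbl
        nb = idx.copy()
        nb[kaxis] += 1 if d[kaxis] > 0 else -1
        outside = nb[kaxis] < 0 or nb[kaxis] >= shape[kaxis]
        if outside or lv.labels[tuple(nb)] == 0:
            packet.position = pos
            return packet, "surface-hit"
        pos[kaxis] += math.copysign(_k.BOUNDARY_EPS, d[kaxis])


# --------------------------------------------------------------------------
# full simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Configuration of one transport run.

    ``scattering_mode``: ``"as-paper"`` feeds the tabulated reduced
    scattering coefficient directly to the kernel as the scattering rate
    (while sampling the anisotropic phase function); ``"physical"``
    un-reduces it first via ``mu_s = mu_s'/(1-g)``.
    """

    volume: LabelVolume
    layout: SourceDetectorLayout
    table: TissueOpticalTable | None = None
    wavelength_nm: int = 800
    n_photons: int = 100_000
    seed: int = 0
    scattering_mode: str = "as-paper"
    gate_ps: float = 1000.0
    fluence_bin_ps: float = 0.0       # 0 disables time-binned fluence export
    ssp_detectors: tuple[int, ...] = ()
    record_paths: bool = False
    path_capacity: int = 4_000_000
    max_segments: int = 16_384
    roulette_enabled: bool = True
    roulette_threshold: float = 1e-4
    roulette_survive: float = 0.1
    validate: bool = True

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.gate_ps <= 0:
            raise ValueError("gate_ps must be > 0")
        if self.fluence_bin_ps < 0:
            raise ValueError("fluence_bin_ps must be >= 0")
        if self.fluence_bin_ps > 0 and self.gate_ps < self.fluence_bin_ps:
            raise ValueError("gate_ps must be >= fluence_bin_ps")
        if not 0.0 < self.roulette_survive <= 1.0:
            raise ValueError("roulette_survive must lie in (0, 1]")
        if self.scattering_mode not in ("as-paper", "physical"):
            raise ValueError(f"unknown scattering_mode {self.scattering_mode!r}")


@dataclass
class SimulationResult:
    """Outputs of one run: detection records (parallel arrays), deposition,
    optional fluence/SSP volumes, detected-photon traversal logs and the
    conservation ledger."""

    config: SimulationConfig
    det_index: np.ndarray          # (n_detected,)
    weight: np.ndarray
    time_ps: np.ndarray
    partial_paths: np.ndarray      # (n_detected, 6) mm per tissue code
    visited: np.ndarray            # (n_detected,) bitmask, bit k = code k
    absorption: ScalarVolume
    ledger: dict[str, float]
    fluence: np.ndarray | None = None       # (n_bins, nx, ny, nz)
    fluence_bin_ps: float = 0.0
    ssp: dict[int, ScalarVolume] = field(default_factory=dict)
    paths: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None  # ptr,vox,len
    n_paths_truncated: int = 0

    @property
    def n_detected(self) -> int:
        return len(self.det_index)

    def records_frame(self) -> pd.DataFrame:
        """Detection records as a table (one row per detected photon)."""
        from ..volumes import TISSUE_NAMES
        cols = {
            "detector": self.det_index,
            "weight": self.weight,
            "time_ps": self.time_ps,
        }
        for code in range(1, 6):
            cols[f"path_{TISSUE_NAMES[code]}_mm"] = self.partial_paths[:, code]
        cols["visited_mask"] = self.visited
        return pd.DataFrame(cols)

    def records_bytes(self) -> bytes:
        """Canonical byte serialization of the records (reproducibility)."""
        return b"".join([
            self.det_index.tobytes(), self.weight.tobytes(),
            self.time_ps.tobytes(), self.partial_paths.tobytes(),
            self.visited.tobytes(),
        ])

    def detected_weight_per_detector(self) -> np.ndarray:
        n = self.config.layout.n_detectors
        out = np.zeros(n)
        np.add.at(out, self.det_index, self.weight)
        return out

    @property
    def conservation_error(self) -> float:
        """Relative gap between launched weight and all ledger sinks."""
        led = self.ledger
        total = (led["deposited"] + led["exit_detected"]
                 + led["exit_undetected"] + led["time_gated"]
                 + led["roulette_net"])
        return abs(led["launched"] - total) / led["launched"]


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Run the time-resolved Monte Carlo transport defined by ``cfg``.

    Identical ``(volume, layout, seed, n_photons, ...)`` give bit-identical
    outputs.  Raises before launch if the source or a detector is off the
    surface (unless ``cfg.validate`` is False).
    """
    lv = cfg.volume
    layout = cfg.layout
    if cfg.validate:
        validate_layout(lv, layout)
    table = cfg.table if cfg.table is not None else build_tissue_table(
        {cfg.wavelength_nm})
    mu_a, mu_s, g_hg, n_refr = table.coefficient_arrays(
        cfg.wavelength_nm, cfg.scattering_mode)

    nx, ny, nz = lv.shape
    hx, hy, hz = lv.voxel_size
    ndet = layout.n_detectors
    det = np.ascontiguousarray(layout.det_centers.reshape(ndet, 3))

    n = int(cfg.n_photons)
    rec_det = np.zeros(n, dtype=np.int32)
    rec_w = np.zeros(n)
    rec_t = np.zeros(n)
    rec_path = np.zeros((n, 6))
    rec_vis = np.zeros(n, dtype=np.uint8)

    absorption = np.zeros(lv.shape)
    if cfg.fluence_bin_ps > 0:
        n_bins = int(math.ceil(cfg.gate_ps / cfg.fluence_bin_ps))
        fluence = np.zeros((n_bins, nx, ny, nz), dtype=np.float32)
    else:
        fluence = np.zeros((0, 1, 1, 1), dtype=np.float32)

    ssp_slot = np.full(ndet, -1, dtype=np.int64)
    ssp_list = sorted(set(int(d) for d in cfg.ssp_detectors))
    for slot, d in enumerate(ssp_list):
        if not 0 <= d < ndet:
            raise ValueError(f"ssp detector index {d} out of range")
        ssp_slot[d] = slot
    ssp = np.zeros((len(ssp_list), nx * ny * nz), dtype=np.float32)

    paths_on = bool(cfg.record_paths)
    cap = cfg.path_capacity if paths_on else 1
    path_vox = np.zeros(cap, dtype=np.int64)
    path_len = np.zeros(cap)
    path_ptr = np.zeros(n + 1, dtype=np.int64)

    seg_vox = np.zeros(cfg.max_segments, dtype=np.int64)
    seg_len = np.zeros(cfg.max_segments)
    ledger = np.zeros(_k.LEDGER_SIZE)

    n_detected, path_end, n_trunc = _k.run_kernel(
        np.ascontiguousarray(lv.labels), hx, hy, hz,
        mu_a, mu_s, g_hg, n_refr,
        np.ascontiguousarray(layout.source_pos),
        np.ascontiguousarray(layout.source_dir),
        det, float(layout.det_radius_mm),
        n, np.uint64(cfg.seed),
        float(cfg.gate_ps),
        bool(cfg.roulette_enabled),
        float(cfg.roulette_threshold), float(cfg.roulette_survive),
        absorption,
        float(cfg.fluence_bin_ps), fluence,
        ssp_slot, ssp,
        paths_on, path_vox, path_len, path_ptr,
        rec_det, rec_w, rec_t, rec_path, rec_vis,
        seg_vox, seg_len,
        ledger,
    )

    led = {
        "launched": float(n),
        "deposited": ledger[_k.LEDGER_DEPOSITED],
        "exit_detected": ledger[_k.LEDGER_EXIT_DETECTED],
        "exit_undetected": ledger[_k.LEDGER_EXIT_UNDETECTED],
        "time_gated": ledger[_k.LEDGER_TIME_GATED],
        "roulette_net": ledger[_k.LEDGER_ROULETTE_NET],
    }
    ssp_volumes = {
        d: ScalarVolume(ssp[slot].reshape(lv.shape).astype(np.float64),
                        voxel_size=lv.voxel_size, origin=lv.origin)
        for d, slot in zip(ssp_list, range(len(ssp_list)))
    }
    return SimulationResult(
        config=cfg,
        det_index=rec_det[:n_detected].copy(),
        weight=rec_w[:n_detected].copy(),
        time_ps=rec_t[:n_detected].copy(),
        partial_paths=rec_path[:n_detected].copy(),
        visited=rec_vis[:n_detected].copy(),
        absorption=ScalarVolume(absorption, voxel_size=lv.voxel_size,
                                origin=lv.origin),
        ledger=led,
        fluence=fluence if cfg.fluence_bin_ps > 0 else None,
        fluence_bin_ps=cfg.fluence_bin_ps,
        ssp=ssp_volumes,
        paths=((path_ptr[: n_detected + 1].copy(), path_vox[:path_end].copy(),
                path_len[:path_end].copy()) if paths_on else None),
        n_paths_truncated=int(n_trunc),
    )
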