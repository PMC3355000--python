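"""Run configuration: YAML schema, validation and the run manifest.

One plain-text config file drives the whole pipeline; its four sections
mirror the computational stages (``phantom``, ``segmentation``,
``simulation``, ``analysis``) plus a master ``seed``, an output directory
and a log level.  Unknown keys are rejected, every defaulted field is
echoed into the run manifest, and all randomness flows from the master
seed, so an output directory is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__ as _version
from .optics import SUPPORTED_WAVELENGTHS


@dataclass
class PhantomSection:
    kind: str = "folded-head"
    grid_shape: tuple[int, int, int] = (256, 256, 92)
    voxel_size_mm: float = 1.0
    scalp_mm: float = 3.0
    skull_mm: float = 7.0
    csf_mm: float = 2.0
    gray_mm: float = 4.0
    semi_axes_mm: tuple[float, float, float] = (85.0, 105.0, 115.0)
    head_top_mm: float = 2.0
    n_sulci: int = 8
    sulcus_width_mm: float = 2.0
    sulcus_depth_mm: float = 8.0
    fissure_width_mm: float = 3.0
    fissure_depth_mm: float = 50.0
    csf_expansion: float = 1.0

    def validate(self) -> None:
        if self.kind not in ("layered-slab", "folded-head"):
            raise ValueError(f"phantom.kind: unknown kind {self.kind!r}")
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ValueError("phantom.grid_shape: three positive integers required")
        if self.voxel_size_mm <= 0:
            raise ValueError("phantom.voxel_size_mm: must be > 0")


@dataclass
class SegmentationSection:
    mu_pen: float = 0.04
    lambda_len: float = 5.0
    nu_area: float = 1.5
    sigma_gauss: float = 1.5
    tau_step: float = 5.0
    eps_reg: float = 1.5
    n_iter: int = 300
    tol: float = 1.0

    def validate(self) -> None:
        if self.mu_pen <= 0 or self.lambda_len <= 0:
            raise ValueError("segmentation: mu_pen and lambda_len must be > 0")
        if self.tau_step * self.mu_pen >= 0.25:
            raise ValueError(
                "segmentation: stability requires tau_step*mu_pen < 0.25")


@dataclass
class SimulationSection:
    wavelength_nm: int = 800
    photons: int = 100_000
    scattering_mode: str = "as-paper"
    view: str = "transverse"
    source_depth_mm: float = 60.0
    separations_cm: tuple[float, ...] = tuple(float(s) for s in range(1, 11))
    detector_radius_mm: float = 1.5
    gate_ps: float = 1000.0
    fluence_bin_ps: float = 0.0
    roulette_threshold: float = 1e-4
    roulette_survive: float = 0.1

    def validate(self) -> None:
        if self.photons < 1:
            raise ValueError("simulation.photons: must be >= 1")
        if self.wavelength_nm not in SUPPORTED_WAVELENGTHS:
            raise ValueError(
                f"simulation.wavelength_nm: {self.wavelength_nm} not in the "
                f"bundled set {set(SUPPORTED_WAVELENGTHS)}")
        if self.scattering_mode not in ("as-paper", "physical"):
            raise ValueError("simulation.scattering_mode: 'as-paper' or 'physical'")
        if self.view not in ("transverse", "sagittal"):
            raise ValueError("simulation.view: 'transverse' or 'sagittal'")
        if self.gate_ps <= 0:
            raise ValueError("simulation.gate_ps: must be > 0")
        if any(b <= a for a, b in zip(self.separations_cm,
                                      self.separations_cm[1:])):
            raise ValueError(
                "simulation.separations_cm: must be strictly increasing")


@dataclass
class AnalysisSection:
    ratio_definition: str = "deepest-layer"

    def validate(self) -> None:
        if self.ratio_definition not in ("deepest-layer", "pathlength"):
            raise ValueError(
                "analysis.ratio_definition: 'deepest-layer' or 'pathlength'")


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    phantom: PhantomSection = field(default_factory=PhantomSection)
    segmentation: SegmentationSection = field(default_factory=SegmentationSection)
    simulation: SimulationSection = field(default_factory=SimulationSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed: must be >= 0")
        for section in (self.phantom, self.segmentation, self.simulation,
                        self.analysis):
            section.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "phantom": PhantomSection,
    "segmentation": SegmentationSection,
    "simulation": SimulationSection,
    "analysis": AnalysisSection,
}


def _build_section(cls, data: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {name!r}; "
            f"valid keys: {sorted(known)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(f.default, tuple) or "tuple" in str(f.type):
                value = tuple(value)
            kwargs[f.name] = value
    return cls(**kwargs)


def parse_config(path: str | Path | None = None,
                 overrides: dict | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``path`` is a YAML file (may be omitted for an all-defaults config);
    ``overrides`` is a flat-or-nested dict applied on top (CLI flags).
    Unknown keys anywhere raise, naming the key; the returned config is
    fully resolved (every field holds a concrete value).
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        data.update(raw)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict):
            data.setdefault(key, {})
            data[key].update(value)
        elif value is not None:
            data[key] = value

    top_known = {"seed", "out_dir", "log_level", *_SECTIONS}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(
            f"unknown top-level config key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(top_known)}")
    cfg = RunConfig(
        seed=int(data.get("seed", 1)),
        out_dir=str(data.get("out_dir", "runs/out")),
        log_level=str(data.get("log_level", "INFO")),
        **{
            name: _build_section(cls, data.get(name, {}) or {}, name)
            for name, cls in _SECTIONS.items()
        },
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: RunConfig, out_dir: str | Path,
                   inputs: dict[str, str | Path] | None = None,
                   extra: dict | None = None) -> Path:
    """Write the run manifest: resolved config, version, wall clock, input
    checksums.  Sufficient to re-run the pipeline bit-identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": {"name": "nirsim", "version": _version},
        "wall_clock_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "config": cfg.to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (inputs or {}).items()
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def config_from_manifest(path: str | Path) -> RunConfig:
    """Rebuild the validated config from a manifest (round-trip identity)."""
    manifest = json.loads(Path(path).read_text())
    return parse_config(overrides=manifest["config"])
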