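"""Delimited-text serialization of detection records, layouts and curves."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import SourceDetectorLayout
from .mc.engine import SimulationResult


def write_records(result: SimulationResult, path: str | Path) -> Path:
    """Detection records as TSV: one row per detected photon."""
    path = Path(path)
    result.records_frame().to_csv(path, sep="\t", index=False)
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"detector", "weight", "time_ps", "visited_mask"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records file lacks columns {sorted(missing)}")
    return df


def write_layout(layout: SourceDetectorLayout, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "source_pos_mm": layout.source_pos.tolist(),
        "source_dir": layout.source_dir.tolist(),
        "det_centers_mm": layout.det_centers.tolist(),
        "det_radius_mm": layout.det_radius_mm,
        "separations_cm": (None if layout.separations_cm is None
                           else layout.separations_cm.tolist()),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_layout(path: str | Path) -> SourceDetectorLayout:
    data = json.loads(Path(path).read_text())
    return SourceDetectorLayout(
        source_pos=np.asarray(data["source_pos_mm"]),
        source_dir=np.asarray(data["source_dir"]),
        det_centers=np.asarray(data["det_centers_mm"]),
        det_radius_mm=float(data["det_radius_mm"]),
        separations_cm=(None if data["separations_cm"] is None
                        else np.asarray(data["separations_cm"])),
    )


def write_curves(curves, path: str | Path) -> Path:
    """Separation curves as TSV (separation_cm, value, wavelength_nm, group)."""
    path = Path(path)
    frames = [c.to_frame() for c in
              (curves.values() if isinstance(curves, dict) else curves)]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path
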