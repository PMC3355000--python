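"""Time-resolved photon-packet transport through the folded head.

Launches 10^5 packets at 800 nm from the frontal surface 6 cm below the
head top, with ten detector disks at 1-10 cm along-surface separation, and
prints the detection statistics and the energy-conservation ledger.
"""

import numpy as np

from nirsim import (
    PhantomSpec,
    SimulationConfig,
    make_folded_head_phantom,
    run_simulation,
    surface_layout,
)

head = make_folded_head_phantom(PhantomSpec())
layout = surface_layout(head, view="transverse", source_depth_mm=60.0)
cfg = SimulationConfig(volume=head, layout=layout, wavelength_nm=800,
                       n_photons=100_000, seed=1)
res = run_simulation(cfg)

print(f"launched {cfg.n_photons} packets; {res.n_detected} detected")
counts = np.bincount(res.det_index, minlength=layout.n_detectors)
weights = res.detected_weight_per_detector()
print("separation[cm]  detections  detected weight")
for sep, n, w in zip(layout.separations_cm, counts, weights):
    print(f"  {sep:>4.0f}          {n:>6}      {w:.4g}")

print("\nconservation ledger (weight units; launched = sum of sinks):")
for key, value in res.ledger.items():
    print(f"  {key:<16} {value:.6f}")
print(f"relative closure error: {res.conservation_error:.2e}")
print("Detected weight falls steeply with separation; arrival times are")
print(f"gated at {cfg.gate_ps:.0f} ps (median detected: "
      f"{np.median(res.time_ps):.0f} ps).")
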