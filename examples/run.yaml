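# Sample run configuration for the nirsim CLI.
# Every omitted key falls back to a documented default and is echoed into
# the run manifest; all randomness flows from the single master seed.
seed: 1
out_dir: runs/demo
log_level: INFO

phantom:
  kind: folded-head          # or layered-slab
  grid_shape: [256, 256, 92] # voxels, 1 mm isotropic
  scalp_mm: 3.0
  skull_mm: 7.0
  csf_mm: 2.0
  gray_mm: 4.0
  csf_expansion: 1.0         # >= 1; widens CSF shell and fissure (atrophy)

segmentation:
  mu_pen: 0.04               # signed-distance penalty weight
  lambda_len: 5.0            # edge-length weight
  nu_area: 1.5               # area weight (shrink pressure)
  sigma_gauss: 1.5           # edge-indicator smoothing (px)
  n_iter: 300

simulation:
  wavelength_nm: 800         # one of 690, 780, 800, 830
  photons: 100000
  scattering_mode: as-paper  # or physical (mu_s = mu_s'/(1-g))
  view: transverse           # or sagittal
  source_depth_mm: 60.0      # frontal surface, below the head top
  separations_cm: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  detector_radius_mm: 1.5
  gate_ps: 1000.0

analysis:
  ratio_definition: deepest-layer   # or pathlength
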