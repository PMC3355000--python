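# Methods

This note documents the models, numerical choices and limitations behind
`nirsim`: a voxelized, time-resolved Monte Carlo simulator of NIRS light
transport in five-layer head models, with an MRI-style segmentation front
end and synthetic-phantom generators standing in for subject data.

## Head model and coordinate conventions

A head model is a 3-D grid of tissue codes (0 air, 1 scalp, 2 skull, 3 CSF,
4 gray matter, 5 white matter) with physical voxel size, 1 mm isotropic by
default on a 256 × 256 × 92 grid (92 axial slices = 9.2 cm of head depth,
slice 0 at the head top). Voxel indices are 0-based; voxel *i* spans the
half-open interval [i, i+1) mm; positions are continuous and labels are
looked up by flooring. The grid exterior is air: every ray that leaves the
grid crosses a surface. This convention also makes slab phantoms (which
fill the whole grid with tissue) well-posed — their faces are the surface —
and it removes the "escaped without an air boundary" failure mode by
construction.

## Tissue optics

Per-tissue coefficients are stored in mm⁻¹ for four wavelengths. The
690/780/830 nm sets are tabulated in the literature in cm⁻¹ and divided by
ten on ingest; white matter deliberately duplicates gray matter at these
bands, as published. The 800 nm set is quoted directly in mm⁻¹. All five
tissues share the anisotropy factor g = 0.92.

Two interpretations of the tabulated scattering values are supported,
because the sources pair a *reduced* coefficient μs′ with an anisotropic
phase function:

* **as-paper** (default): the transport kernel scatters at the rate μs′ as
  printed while sampling Henyey–Greenstein with g = 0.92. This reproduces
  the published configuration literally.
* **physical**: the rate is un-reduced first, μs = μs′/(1−g), which is the
  standard similarity relation; at g = 0.92 rates grow 12.5-fold and runs
  are correspondingly slower.

Refractive indices are not part of the published tables; the package
defaults to n = 1.4 for all tissues and 1.0 for air (the standard
soft-tissue convention) and accepts per-tissue overrides. With a uniform
tissue index, Fresnel/Snell physics acts only at the air interface;
per-tissue indices switch on internal refraction at tissue boundaries.

## Monte Carlo transport

Each photon packet starts at the source with weight 1 and an inward
direction, nudged 10⁻⁶ mm into the first voxel (no specular launch
deduction; sources are modeled as already coupled into tissue). The loop:

1. **Free path.** Draw an optical-depth budget −ln(1−ξ), with ξ ∈ [0, 1)
   from the per-photon RNG, and march the ray voxel by voxel using exact
   axis-plane crossing distances, consuming μt·s per segment. Positions are
   nudged 10⁻⁹ mm across each face to avoid re-intersection; path-length
   and time bookkeeping use the exact geometric distances, so partial paths
   are nudge-free.
2. **Interaction.** Where the budget runs out, deposit Δw = w·μa/μt into
   the voxel, then rotate the direction by a Henyey–Greenstein polar angle
   (closed-form inverse CDF; cos θ = 2ξ−1 at g = 0) and a uniform azimuth,
   using the standard local-frame construction.
3. **Clear media.** In voxels with μs = 0 the discrete interaction scheme
   is undefined (an event would deposit the whole weight). Such voxels are
   treated as continuously absorbing: the weight decays by exp(−μa·s)
   along the segment with the loss deposited locally, and no budget is
   consumed. This is exact (a pure absorber transmits e^(−μa·L) to float
   precision) and never triggers for the bundled tissues, whose μs > 0.
4. **Boundaries.** At a refractive-index step the unpolarized Fresnel
   reflectance R is computed; beyond the critical angle the packet reflects
   deterministically, otherwise it reflects with probability R or is
   transmitted with its full current weight (binary survival — simpler
   detector statistics, unbiased). Exits into air are tested against the
   detector disks (default radius 1.5 mm, flush with the surface, all exit
   angles accepted) and recorded or tallied as undetected.
5. **Termination.** Packets exceeding the time gate (default 1000 ps,
   speed c/n with c = 0.299792458 mm/ps) are terminated with their residual
   weight logged; below the roulette threshold (default 10⁻⁴) packets
   survive with probability 0.1 and a 10× weight boost, or terminate.
   All sinks — deposition, detected and undetected exits, gate and
   roulette — land in a ledger whose sum equals the launched weight to
   ≈10⁻¹² relative error on every tested configuration.

**Randomness and reproducibility.** Each photon owns a splitmix64 counter
stream seeded from (master seed, photon index). Results are therefore
bit-identical for a given seed regardless of how photons would be batched,
and two runs with the same configuration produce byte-identical detection
records.

**Bookkeeping.** Per packet: per-tissue partial path lengths (mm), a
visited-layer bitmask, elapsed time Σ s·n/c. Optionally: per-voxel
time-binned traversal weight (a movie-style fluence export), kernel-side
spatial-sensitivity accumulation for selected detectors, and a CSR log of
every detected photon's voxel segments for offline SSP work. The
per-photon segment buffer holds 16384 entries — comfortably above the
~3000 segments a packet can accrue within the 1000 ps gate at the largest
bundled extinction rates; overflowing photons are flagged, not silently
truncated.

## Source–detector layouts

Probe rows follow the head surface: the source sits on the frontal surface
(default 6 cm below the head top) and detectors at 1–10 cm *along-surface*
separation, in the axial plane (transverse row) or the midline plane
(sagittal row). Positions come from walking the iso-contour of the head
mask in the chosen plane and interpolating at the requested arc lengths;
the source is snapped along its inward normal to just inside the first
tissue voxel. Slab phantoms use a straight row on the illuminated face.
Layout validation (source and detectors within ~1.5 voxels of an
air–tissue boundary, source direction entering tissue) runs before launch.

## Analysis

* **Intensity vs separation**: total detected weight per detector;
  detectors with no detections keep explicit zeros.
* **Layer-ratio curves**: the detected weight at each separation is
  partitioned by the deepest layer visited — *surface* (scalp/skull only),
  *CSF* (reached CSF but not the brain), *cortex* (reached gray or white
  matter). The three fractions sum to one by construction; separations
  with zero detected weight are flagged undefined. The published ratio
  curves are not operationally defined in their source; this partition is
  the primary definition because it makes the curves a partition of unity
  and "signal from the cortex" unambiguous. A per-photon pathlength-share
  variant (`definition="pathlength"`) is available for comparison.
* **Cross-point**: the separation where (cortex − surface) changes sign,
  linearly interpolated on the separation grid; multiple crossings return
  the smallest with a flag, no crossing returns an absent-value status.
* **SSP**: per-voxel accumulated (path length × exit weight) of detected
  photons, per detector, optionally normalized to unit sum. Kernel-side
  accumulation and the offline log-based route agree to float32 precision
  and are cross-checked in the tests.
* **Multi-wavelength**: the same geometry re-run per wavelength with
  per-wavelength seeds derived from the master seed.

## Segmentation

The five-layer segmentation is a two-step pipeline on T1-like contrast
(CSF darkest intracranial class, then gray, then white matter; skull dark,
scalp bright — the component-to-tissue mapping is configurable for other
orderings).

**Geometry step, per axial slice.** Distance-regularized level sets
(energy μP(φ) + λL_g(φ) + νA_g(φ), cosine-regularized Dirac of width
ε = 1.5 px, explicit time step with τμ < 0.25, no re-initialization)
shrink a contour from the image border onto the scalp outer edge, then
onto the scalp/skull interface, then onto the inner skull wall. Two
details matter in practice and are deliberate design choices:

* *Edge masking.* A contour initialized just inside an already-found edge
  is recaptured by that edge's attraction basin (Gaussian smoothing widens
  it to ≈2σ px). Before each inner evolution the exterior of the previous
  region is flattened to the median intensity of an interior band, which
  deletes the found edge from the edge-indicator field, so the contour
  locks onto the *next* interface.
* *Posterior snapping.* Level-set contours are accurate to ~1–2 px; the
  final interfaces are refined to voxel precision by reclassifying a ±2 px
  band with Gaussian class models (median/MAD statistics from the ring
  cores — robust to the contamination a misplaced rough contour causes).

Region growing (seeded flood fill, first-seed-wins on shared components)
then labels the scalp and skull rings. All 3-D morphology uses an in-plane
structuring element, consistent with the slice-wise design.

**Intensity step.** A three-component 1-D Gaussian mixture is fitted to
the intracranial intensities by EM (log-likelihood monotone by
construction, variance floor against collapse, two deterministic starts —
quantile and linspace means — keeping the better likelihood, since a
single quantile start can merge two components on strongly unbalanced
class sizes). Components map to CSF/gray/white by ascending mean; each
intracranial voxel takes its maximum-posterior tissue, ties toward the
lower code.

The paper trail for this pipeline gives neither parameter values, seed
placement, nor the 2-D→3-D assembly; all such choices above are the
package's own, and bias-field correction and atlas registration are
deliberately out of scope (synthetic inputs are bias-free).

## Synthetic data: what it emulates, what it does not

The **folded-head phantom** is the upper half of concentric ellipsoidal
shells (default semi-axes 85/105/115 mm; scalp 3, skull 7, CSF 2, gray
matter 4 mm over a white-matter core) with planar CSF-filled sulcal
grooves through the cortex and a midline interhemispheric fissure; a
CSF-expansion factor ≥ 1 widens the CSF shell and fissure to emulate the
enlarged CSF spaces of brain atrophy. Layer thicknesses are assigned by
Euclidean distance from the outer surface, so shells are watertight and
layer geometry is exact; the bottom cut plane is not treated as surface.
Default thicknesses are the bundled study conditions; they are thinner
than an average adult's scalp+skull, which is one reason the phantom's
surface/cortex cross-point (≈2.3–2.4 cm) sits below the ≈3 cm range
expected for adult heads. The **layered slab** reproduces the classic
five-layer benchmark with exact thickness-times-area voxel counts.

The **synthetic T1 generator** draws each voxel from the Gaussian of its
tissue class. It emulates class contrast and additive noise only: no bias
field, no partial-volume mixing, no anatomical texture, no scanner
artifacts. Segmentation scores on it therefore demonstrate the pipeline's
correctness under its stated model, not clinical-grade performance on real
MRI.

Monte Carlo tests at 10⁴–10⁶ photons are scaled-down study conditions
(the study itself quotes 2×10⁷ photon trajectories); the quantities
asserted on phantom runs — curve crossings, group fractions, monotonicity
— are stable at 10⁶ packets (the acceptance run repeats within ~1% across
seeds).

## Numerical tolerances and degenerate inputs

* Energy conservation is asserted at 10⁻⁹ relative (measured ~10⁻¹²).
* The time-resolved reflectance peak on a homogeneous semi-infinite medium
  is compared with the diffusion closed form R ∝ t^(−5/2)
  exp(−(ρ²+z0²)/(4Dct) − μa c t) averaged over the detector disk; a ring
  of 8 disks at equal separation supplies the statistics. Agreement is
  well inside the 15% band expected of the diffusion approximation.
* Degenerate inputs raise informative errors: unsupported wavelengths,
  tissue codes outside 0–5, sources/detectors off the surface, constant
  images (no contour), seeds on background, K larger than the number of
  distinct intensities.
* Curve values at separations with zero detections are NaN with an
  explicit `undefined` flag, never silently dropped; the cross-point
  search skips them.

## Known limitations

* No polarization, fluorescence, mesh geometry, GPU kernels, or variance
  reduction beyond Russian roulette.
* The detector aperture (1.5 mm disk, all angles) and refractive-index
  defaults are conventions, not published values; both are configurable.
* The serial kernel favours reproducibility over parallel speed; ~10⁶
  packets per minute on one CPU core for the bundled head at 800 nm.
* Sulci and fissure are planar slots, not folded cortical sheets; they
  reproduce the CSF-channel light-guiding effect qualitatively only.
* The hemodynamic layer (oxy/deoxy-hemoglobin spectroscopy) and image
  reconstruction are out of scope.
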