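# Methods

This note documents the models, numerical choices and limitations of the
`wvt` package, module by module.

## Imaging geometry (`wvt.optics`)

The block face is illuminated through a single objective whose axial
chromatic aberration separates the blue illumination focal plane from the
green/red one by `axial_chromatic_separation` (default 10 μm, an instrument
measurement).  Nuclear counterstain applied in real time to the freshly cut
surface penetrates only a few μm; its crosstalk into the green channel
reaches the noise floor at `crosstalk_free_depth` = 4 μm.  Two schemes are
encoded:

- **conjugated** — every detection plane conjugate to its illumination
  plane: blue detection depth = green depth + chromatic separation
  (4 + 10 = 14 μm with the defaults, where no counterstain remains);
- **optimized** — the blue camera moved so its detection plane sits at the
  surface, i.e. one crosstalk-free depth above the green plane
  (4 − 4 = 0 μm), where the counterstain is strongest.

A negative computed depth means the plane is above the block face; it is
flagged (`out_of_sample`), not raised, because the instrument can still
acquire there.

Resolution is measured empirically on sub-diffraction beads: per isolated
bead, a lateral (x) and an axial (z) line profile through the intensity
maximum is fitted with a four-parameter Gaussian (amplitude, center, σ,
constant offset — the offset because real backgrounds are nonzero), and
FWHM = 2√(2 ln 2)·σ ≈ 2.3548 σ.  Beads with another local maximum within 3×
the nominal FWHM are excluded as merged objects; the axial profile is cut at
the quadratically interpolated lateral peak.  Aggregation is mean ± s.e.m.
(sd/√n, 0 for n = 1).  No diffraction/PSF physics is modeled — measurement
only.

## Reconstruction (`wvt.reconstruction`)

The three-phase demodulation formula `½√((I₀−I₂)² + (2I₁−I₀−I₂)²)` is the
exact amplitude estimator for a π/2 phase step: with
`I_k = A + B·cos(φ + kπ/2)`, the two quadratures are `I₀−I₂ = 2B cos φ` and
`2I₁−I₀−I₂ = −2B sin φ`.  Consequences relied on by the tests: output is
non-negative by construction (no clipping needed), invariant to any constant
added to all three raws (optical sectioning), homogeneous of degree 1 in the
raws, and independent of the local fringe phase.  Wide-field reconstruction
is the plain sum (photon-count semantics; `mean=True` divides by 3 for
display).  Saturated raw pixels (65535 in integer input) are propagated and
flagged in a mask, never repaired.  The default channel→mode map is
green/red→SIM, blue→WF; overrides are honored with a warning.  No inter-tile
intensity normalization is applied.

## Registration (`wvt.registration`)

Model: 2-D similarity (dx, dy, rotation, isotropic scale), pivoted at the
image center because the channels share an optical axis.  Estimation is
derivative-free on the normalized cross-correlation objective: a 5×5 coarse
grid over rotation (±1°) × scale (±1%), each node's translation solved by
sub-pixel phase correlation, followed by Nelder–Mead refinement of all four
parameters (initial simplex steps 0.5 px, 0.05°, 0.001; xatol 1e-4).  The
returned transform is the *correction* mapping the moving channel onto the
fixed (green) reference — the quantity the instrument records once per
optical configuration and applies to every tile of a dataset.  Correlation
below a floor (default 0.2) or a structureless image raises a registration
error.  Warping is bilinear by default (bicubic via `order=3`), out-of-bounds
zero-filled and maskable.  The identity transform bypasses interpolation
entirely so an untouched channel is bit-identical.

Co-location error is measured at the field center and four corners by
windowed cross-correlation (default 128 px windows; the window size is a free
choice, exposed as a parameter).  Windows are Hann-apodized before the
phase-correlation: without apodization, spectral leakage on quasi-periodic
content (concentric rings) biases the sub-pixel peak by up to a pixel at the
corners.  Flat windows are skipped with a warning.

Axial (z) registration between channels is deliberately absent: it is
handled physically by the detection-plane scheme, not by image warping.
Nonrigid registration is out of scope.

## Contour recognition and planning (`wvt.contour`)

Pipeline on the ~1.68 μm/px DAPI preview: median filter (3 px) → threshold →
morphological opening (disk radius 3 px ≈ 5 μm, removing sectioning debris
smaller than ~10 μm while preserving the cortical boundary) → connected-
component filtering → hole filling → boundary of the largest survivor.
Numerical choices where the procedure admits alternatives:

- **Threshold**: Otsu on the median-filtered image by default; real-time
  counterstaining yields uniform layer-to-layer contrast, which is what makes
  Otsu stable.  A fixed threshold is available for pathological histograms.
- **Fragment rejection** realizes "drop large debris far from the tissue":
  components other than the largest are kept only if their area ≥ 64 px²
  *and* their centroid lies within (largest component's bounding radius +
  500 μm) of its centroid.  This is deliberately conservative: near-tissue
  structure is never dropped.
- **Noise guard**: if the largest surviving component is smaller than
  `min_tissue_area_px` (500 px ≈ 1.4·10³ μm²), the layer is declared empty —
  a flag, not an error; the planner then reuses the previous layer's region.
- **Hole filling** is a full flood-fill from the border complement, so
  ventricles of any size are restored into the tissue mask.

Planning: the minimum imaging rectangle is the contour's circumscribed
rectangle expanded by `margin` = 288 μm (half a FOV) on each side; the
margin absorbs layer-to-layer growth and slight under-segmentation.  The
mosaic lattice (FOV 576 μm, overlap 5 μm, stride 571 μm, FOV-center stage
coordinates, 0-based indices) is anchored once per dataset and never
re-anchored, so per-layer regions are index ranges on one lattice and the
stack self-registers.  The grid span is the smallest *anchored* contiguous
run covering the rectangle: `i₀ = ⌊(xmin − origin + fov/2)/stride⌋`,
`i₁ = ⌈(xmax − origin − fov/2)/stride⌉` — which can exceed the free-placement
minimum `1 + ⌈(extent − fov)/stride⌉` by one when the rectangle straddles the
lattice unfavorably.  The symmetric smallest cover is used; per-side
asymmetric shrinking is not attempted.  The region for layer k+1 derives
from the contour of layer k (the preview exists only after the cut); layer 1
uses a configured full-coverage region, by default the whole preview frame.
Rectangles beyond configurable stage travel limits raise a planning error in
single-layer planning and are clipped with a warning in whole-brain planning.

Stitching places tiles at lattice positions and feathers the overlap strips
with a linear ramp (minimum weight 1/(overlap+1), so outer borders stay
defined); weighted averaging preserves constants exactly and leaves no
double edge at seams.  Missing tiles are zero-filled.

## Accounting (`wvt.accounting`)

Sizes use binary units (MB = 2²⁰ B, TB = 2⁴⁰ B) — these are the units under
which an 1800² 16-bit tile is 6.18 MB; decimal units are behind
`binary=False`.  Dataset size counts one stored reconstruction per mosaic
per channel (phase raws are transient).  Imaging time uses the per-channel
mosaic count because the channels expose simultaneously.  The mosaic
reduction of a plan is reported under *both* aggregations — ratio of totals
and mean of per-layer ratios — because they differ whenever layer sizes
vary, and a multi-brain average of per-brain ratios is not recoverable from
summed totals.

## Quantification (`wvt.quantify`)

Somas are matched across channels by **mutual nearest neighbors with a
strict 3-D Euclidean cutoff of 1 μm** (a pair at exactly 1.0 μm is rejected).
Mutual-NN guarantees one-to-one matching — no soma can claim two partners —
which is what a manual proofreading pass would also enforce.  Coordinates
are in μm throughout, so anisotropic voxels (1 × 1 × 2 μm³ at detection) are
absorbed before matching.

The blob detector is plumbing, not a contribution: blockwise (default 512³
voxels, 16-voxel halo) single-scale scale-normalized Laplacian-of-Gaussian
filtering at the soma scale (σ = 4 μm isotropic in sample space), local
maxima above a threshold relative to the volume's peak response (for a
matched Gaussian blob the peak response ≈ its amplitude), and a 3 μm
brightest-wins merge that also deduplicates halo double-detections.  It is
calibrated for well-separated Gaussian-like somas on synthetic volumes;
densely packed or irregular real somas are the province of dedicated tools.

Region counting floors each soma coordinate to its atlas voxel (deterministic
boundary convention), counts label-0 somas in an `unassigned` bin with a
warning, rolls sub-regions up to parents on demand (parent proportions equal
the sum of their children's by construction), and aggregates across brains
as mean ± s.e.m. of per-brain proportions, treating a region absent from one
brain as 0% there.  Proportions of an empty channel are NaN, not zero.

## Synthetic data (`wvt.synthetic`)

The generators define the study conditions; everything is deterministic
under the spec seed.

- **Coronal sections**: wobbled superellipse tissue (exponent 2.5, random
  ±10° orientation, center jitter), a ventricle-like hole (~18% of the
  semi-axes), 3 debris fragments (10–26 px) scattered strictly outside the
  tissue, nuclei as bright dots at 1500 /mm² over a diffuse tissue level
  (400 vs 100 background), Gaussian read noise σ = 20.  Ground truth is the
  *filled* tissue mask, matching how the contour stage defines tissue.
- **Phantom brains**: 6 layers by default with a half-sine
  anterior–posterior taper (min 45% of the maximal semi-axes), emulating a
  coronal series that grows and shrinks.
- **Fringe modulation**: the DMD's binary fringes are modeled as sinusoids —
  the objective low-pass filters the square wave and only the fundamental
  survives demodulation.  Field curvature is modeled phenomenologically: the
  out-of-focus term gains fringe contrast ∝ (field radius)², reproducing
  crosstalk that is strongest at the field edge and absent on axis.  The
  surface confinement of the counterstain is an exponential depth decay with
  length `confinement/3` (≈5% at 4 μm).
- **Soma populations**: a planted fraction of green somas (default 0.22%,
  the scale of interest for doubly labeled neurons) gets a red twin within
  0.8 μm; all other somas keep ≥ 5 μm apart (spatial-hash rejection
  sampling), so the planted pairs are exactly the mutual-NN pairs under the
  1 μm rule and recovery is checkable as set equality.
- **Bead fields**: Gaussian emitters (σ 0.20 μm lateral / 1.0 μm axial at
  0.32 × 0.32 × 0.2 μm³ voxels) with enforced 3×FWHM separation, optional
  shot/read noise.
- **Atlases**: equal slabs along x with a two-level hierarchy, generated
  pre-aligned in the data frame — deformation registration to a reference
  atlas is explicitly out of scope, so region counting is tested on ground
  truth labels only.

What the phantoms do *not* emulate: optical PSFs and scattering, staining
kinetics beyond depth confinement, tissue deformation, non-Gaussian soma
shapes, intensity inhomogeneity across a section.  Green tests therefore
validate the algorithms' correctness under their stated models, not their
robustness to every artifact of real acquisitions.

## Problem sizes

Validation runs at desk scale by design: 256²-px ring targets (0.32 μm/px)
with 20 random misalignments for the registration envelope; 50 random
700×1000-px coronal phantoms (1.68 μm/px) for contour recognition; 6-layer
tapered phantoms for planning; 10 seeds × 10,000 green somas
(coordinate-level) for the co-location fraction; a 64×256×256 volume with
200 planted somas for the detector.  These sizes keep the full suite in a
few minutes while leaving every statistical check comfortably powered.

## Known limitations

- The contour stage assumes one dominant tissue piece per layer; two
  far-separated pieces (e.g. severed olfactory bulbs) would keep only the
  larger.
- Registration assumes the misalignment lies within the stated envelope
  (±10 px, ±1°, ±1% scale); larger errors need a wider coarse grid.
- On rotationally symmetric calibration targets the rotation component is
  weakly observable; the bundled ring target carries faint radial spokes for
  that reason, and residuals are always validated by displacement probes
  rather than by parameter comparison alone.
- The soma detector's threshold is relative to the volume's global maximum
  and assumes roughly uniform soma brightness; strongly varying intensity
  would need per-block normalization.
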