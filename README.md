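# wvt — multicolor wide-field large-volume tomography pipeline

Block-face whole-brain tomography alternates mosaic optical imaging with
mechanical sectioning: every freshly cut coronal face is imaged tile by tile,
then shaved off, for thousands of layers.  Running three color channels
simultaneously — blue nuclear counterstain (DAPI) for cytoarchitecture, green
and red fluorescent proteins for the neurons of interest — makes the method a
tool for comparing two labeled populations *in the same brain*, but it raises
three computational problems that this package solves:

1. **Reconstruction.** Each field of view is acquired three times under a
   sinusoidal fringe pattern stepped by π/2.  Writing the raws as
   `I_k = A + B·cos(φ + kπ/2)`, the optically sectioned (OS-SIM) image is the
   pixelwise demodulation

   `I_SIM = ½·√((I₀ − I₂)² + (2I₁ − I₀ − I₂)²)`

   which returns the in-focus modulated amplitude `B` exactly and cancels the
   unmodulated out-of-focus term `A`.  The wide-field image is the plain
   superposition `I₀ + I₁ + I₂`.  Because axial chromatic aberration separates
   the blue and green/red illumination planes (≈10 μm) while the counterstain
   only penetrates ≈4 μm of the cut face, the optimal scheme detects green/red
   at 4 μm depth with SIM and blue at the surface with WF — the package
   encodes this plane arithmetic (`wvt.optics`).

2. **Chromatic co-registration.** The three cameras differ by a small lateral
   similarity transform (shift, rotation about the optical axis, isotropic
   scale).  `wvt.registration` fits the transform on a structured calibration
   target by maximizing normalized cross-correlation (coarse rotation×scale
   grid with phase-correlation translation, then Nelder–Mead refinement) and
   applies it to every tile, bringing the residual co-location error at the
   field center and corners below one pixel (0.32 μm).

3. **Acquisition planning.** Instead of imaging a fixed cuboid sized to the
   brain's largest cross-section, `wvt.contour` recognizes the tissue contour
   of each layer from the DAPI preview (median filter → Otsu threshold →
   morphological opening → fragment rejection → hole filling) and plans the
   next layer's acquisition as the smallest run of mosaic-lattice columns and
   rows covering the contour's circumscribed rectangle expanded by a 288 μm
   safety margin (half a 576 μm field of view; lattice stride 571 μm from the
   5 μm tile overlap).  `wvt.accounting` turns mosaic counts into data volume,
   imaging time and camera/DMD wear.

Downstream, `wvt.quantify` identifies doubly labeled neurons as green/red
soma pairs at 3-D distance strictly < 1 μm (mutual nearest neighbors), counts
somas per atlas region with a two-level hierarchy rollup, and aggregates
per-brain proportions as mean ± s.e.m.  `wvt.synthetic` generates all the
phantoms — coronal sections with ventricles and sectioning debris, fringe
triplets, misaligned calibration targets, bead fields, soma populations with
a planted co-location fraction — with exact ground truth, so the whole
pipeline is testable without any instrument data.

## Worked example

Acquisition arithmetic from per-channel mosaic counts (a whole mouse brain
with and without contour-driven planning):

```sh
$ wvt account --mosaics-without 858701 --mosaics-with 546310
{
  "mosaics_per_channel_without": 858701,
  "mosaics_per_channel_with": 546310,
  "tile_size_mb": 6.18,
  "dataset_size_tb_without": 15.2,
  "dataset_size_tb_with": 9.7,
  "imaging_time_h_without": 81.7,
  "imaging_time_h_with": 52.0,
  "exposure_reduction": 937173,
  "reduction_pct_ratio_of_totals": 36.4
}
```

Each 1800×1800 16-bit mosaic is 6.18 MB; three channels of 858,701 mosaics
are 15.2 TB and take 81.7 h at 342.5 ms per mosaic, falling to 9.7 TB and
52.0 h when contour recognition trims the per-layer grids; the camera
exposure / DMD flip count drops by 3 × the mosaic reduction = 937,173.

Planning a six-layer tapered phantom brain end to end:

```python
from wvt import synthetic, contour, accounting

phantom = synthetic.generate_phantom(synthetic.PhantomSpec(
    seed=11, n_layers=6, shape=(350, 500), max_semi_axes_um=(330, 230)))
plan = contour.plan_whole_brain(phantom.dapi_layers,
                                contour.MosaicSpec(), contour.ContourParams())
print(accounting.summarize_plan(plan))
```

prints per-layer mosaic counts `[4, 6, 6, 6, 6, 6]` — 34 mosaics with
recognition versus 36 with the fixed maximal region, a 5.6% reduction under
both aggregation modes (ratio of totals and mean of per-layer ratios).  The
reduction grows with how strongly the sample tapers; the desk-scale phantom
is deliberately mild.

A full synthetic run (`wvt run --seed 0 --out demo/`) chains simulation,
reconstruction, registration, planning, co-location and region counting and
writes per-stage JSON reports.

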