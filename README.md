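# ntpipe

Quantitative image analysis for membrane-nanotube microscopy.

Membrane nanotubes (tunneling nanotubes) are thin (< 1 µm) membranous
cytosolic bridges that connect cells over tens of micrometres, suspended
above the substrate. They transmit Ca²⁺ signals between cells and carry
vesicular cargo at motor-protein speeds. Imaging them demands gentle,
fast volumetric microscopy — stage-scanned (lattice) light-sheet imaging
for 3D structure, widefield movies for Ca²⁺ dynamics and transport — and
each modality needs its own quantification. `ntpipe` implements that
quantification as a tested, reusable pipeline for researchers working on
intercellular communication:

- **synthetic data** — phantom generators for all three acquisition
  modes (3D scenes of membrane-labelled cells joined by sub-resolution
  tubes imaged through a Gaussian PSF/sheet model with 45° diagonal
  slicing; Ca²⁺ uncaging movies with stimulated, nanotube-connected and
  bystander cells; puncta-transport movies), each exporting exact ground
  truth so every downstream stage is testable without real data;
- **deskew** — reconstruction of orthogonal x,y,z volumes from
  stage-scanned diagonal slice stacks (slice *k* shifts by
  *k·s·*cos θ laterally and sits at depth *k·s·*sin θ), plus
  maximum-intensity top/side projections;
- **morphometry** — seeded minimal-cost ridge tracing of nanotubes,
  cell-to-cell arc length *L*, transverse linescan widths fitted as
  Gaussian + offset with FWHM = 2√(2 ln 2)·σ, substrate vs cell–cell
  contact classification, and cohort summaries (mean ± s.d., length
  histograms);
- **calcium** — background subtraction, per-pixel ΔF/F₀ = (F−B)/F₀ − 1
  with F₀ the mean of 100 pre-stimulus frames, ROI traces, peak
  amplitude, peak-to-peak lag, k·σ responder classification, band
  kymographs (time × distance), Ca²⁺ initiation-site distance from the
  nanotube contact point, and a paired Student's t-test helper;
- **tracking** — Laplacian-of-Gaussian spot detection with sub-pixel
  refinement, globally optimal motion-predictive linking, projection
  onto the tube path to get s(t), mean track velocity
  |s(end) − s(start)|/duration in µm/min, and directed vs diffusive
  classification from straightness and the MSD exponent α.

## Worked example

Render a sub-resolution nanotube through the default optics (460 nm
lateral PSF, 1.2 µm sheet, 105 nm pixels), trace it, and measure it:

```python
from ntpipe import OpticsModel, render_scene
from ntpipe import morphometry as mm
from ntpipe.pipeline import single_tube_scene

optics = OpticsModel()  # 460 nm PSF, 1.2 um sheet, 105 nm pixels, 45 deg scan
scene, seed_a, seed_b = single_tube_scene(length_um=14.85, diameter_nm=150.0)
volume = render_scene(scene, optics)
path = mm.trace_path(volume, seed_a, seed_b)
profile = mm.fit_fwhm(mm.transverse_profile(volume, path, path.length_um / 2))
print(f"traced length: {path.length_um:.2f} um")
print(f"transverse FWHM: {profile.fwhm_nm:.0f} nm (R^2 = {profile.r_squared:.3f})")
print(f"contact class: {mm.classify_contact(path, substrate_z=0.0)}")
```

prints

```
traced length: 14.92 um
transverse FWHM: 469 nm (R^2 = 1.000)
contact class: cell_cell
```

The traced length recovers the 14.85 µm ground truth to half a per
cent. The fitted width is the *optical* width: a 150 nm tube convolved
with a 460 nm PSF measures ≈ 469 nm — sub-resolution tubes report the
PSF, not their physical diameter, which is why apparent nanotube widths
cluster at the resolution limit.

## Command line

End-to-end runs are driven by one YAML config (see
`ntpipe.config.DEFAULTS` for every key; unknown keys are errors):

```bash
ntpipe run --mode all --seed 0 --out results/        # simulate -> analyse, all modes
ntpipe deskew --input stack.tif --meta stack.json --out volume.tif
ntpipe morphometry --volume volume.tif --seeds seeds.csv --out results/
ntpipe calcium --movie m.tif --rois rois.json --out results/
ntpipe track --movie m.tif --path path.csv --out results/
```

Each run writes per-stage artifacts (TIFF + JSON sidecars, CSV tables),
a machine-readable `summary.json` and a human-readable `report.txt`;
re-running with the same config and seed reproduces every output
byte-for-byte.

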