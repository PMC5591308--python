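# Methods

This note records the models implemented in `ntpipe`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate about real recordings.

## Image formation model

Optics are summarised by a Gaussian lateral PSF (default FWHM 460 nm)
and a Gaussian axial response set by the illumination-sheet thickness
(default FWHM 1.2 µm); FWHM = 2√(2 ln 2)·σ throughout. There is no
Bessel-lattice field simulation, no aberrations and no photobleaching —
the generators target the *analysis* pipeline, not instrument physics.

Nanotubes are modelled as filled cylinders of uniform membrane-stain
density, not hollow annuli: after convolution with a PSF several times
wider than the tube the two are indistinguishable, and the filled disk
has a convenient closed quadrature. The blurred cross-section is
computed as the exact radial convolution of a disk with the lateral
Gaussian (a Rice-distribution integral, validated in the tests against
a brute-force 2D grid convolution), multiplied by an axial Gaussian at
the sheet σ. This factorisation is exact for tubes lying in the lateral
plane and for point sources; tubes are assumed roughly horizontal,
which matches their suspended-above-the-substrate geometry. Cell-body
ellipsoids get a soft erf edge at the lateral σ — adequate, since no
measurement is taken on cell-body boundaries.

Both the orthogonal renderer and the diagonal-acquisition simulator
evaluate this same analytic scene density, the former on the deskewed
output grid, the latter on the sheared slice planes of a stage scan
(slice k, pixel (i, j) ↦ world (j·p + k·s·cos θ, i·p, k·s·sin θ) for
pixel pitch p, step s, angle θ). Deskewing a simulated acquisition must
therefore reproduce the rendered volume up to interpolation error; the
suite requires normalized cross-correlation > 0.99 noise-free.

Noise, when enabled, is Poisson on the signal plus additive Gaussian
read noise (σ configurable, default 2 counts), clipped at zero; `none`
gives deterministic fixtures. Every generator is a pure function of
(parameters, seed).

## Deskew

Axes: 0-based indices, world coordinates in µm, x the in-plane scan
axis, z the detection/depth axis. Each slice is translated along x by
k·s·cos θ (generally a non-integer pixel count) and placed at depth
k·s·sin θ. The default shear applies linear-weight splatting, which for
a pure translation equals linear interpolation and conserves total
intensity exactly; `nearest` is kept for exactness tests. Output
spacing is p laterally and s·sin θ axially (anisotropic; isotropic
resampling is deliberately a separate post-step). Voxels that received
no or only partial splat weight are flagged in a validity mask, and
projections ignore them — the edge columns of each sheared slice
receive partial weight only, and treating them as valid visibly
corrupts round-trip comparisons.

## Nanotube tracing and morphometry

Tracing is seeded (two endpoint seeds per tube): the minimal-cost path
through cost = 1/(10⁻³ + I/I_max) is found by Dijkstra search with
geometric step weights, then refined by four rounds of alternately
re-centring every interior station on the intensity centroid in its
perpendicular plane (±0.4 µm window, symmetric so the centroid is
unbiased) and smoothing with a 3-point moving average, endpoints held
fixed. The refinement relaxes the voxel-quantised chain onto the
continuous ridge; it removes both stair-step inflation and corner
cutting (an L-shaped tube traces within 2% of truth, a straight tube
within 0.5% with sub-voxel RMS deviation). Lengths are seed-to-seed
arc lengths along the refined polyline; where the membrane edge ends
and the cell begins is not otherwise defined.

Transverse profiles are sampled in the lateral plane only, perpendicular
to the local tangent, at the lateral voxel pitch, with cubic spline
interpolation — bilinear sampling adds ~2% width broadening, cubic is
negligible. Widths come from a Gaussian + constant-offset least-squares
fit; fits with R² < 0.8, flat profiles or multi-peaked profiles are
rejected. Below the resolution limit the fitted FWHM converges to the
PSF FWHM (the suite requires agreement within 3%), so reported widths
are optical, never physical diameters; no deconvolution or
super-resolution estimation is attempted.

Contact classification is by endpoint height: substrate if either
endpoint is within z_tol (default 0.5 µm) of the substrate plane, with
the boundary inclusive (≤). Cohort summaries report mean, s.d.
(n − 1 denominator, missing for n = 1) and s.e.m. — both spreads are
labelled because conventions differ between reports — plus a length
histogram with 2 µm default bins.

## Ca²⁺ analysis

Normalisation follows the standard uncaging workflow: subtract a
background estimate B (a scalar from a cell-free region, or a per-pixel
image; the generators record the true background), then divide by the
per-pixel mean F₀ of the 100 frames preceding the stimulus:
ΔF/F₀ = (F − B)/F₀ − 1. Pixels with F₀ ≤ ε are flagged invalid and
excluded from ROI means. ROIs are user-supplied polygons; there is no
automatic segmentation.

Peak amplitude is the change from the baseline immediately preceding
the event (mean of the 20 frames before the first sustained departure
from the pre-stimulus level) to the trace maximum; argmax ties resolve
to the earliest frame. Lag is peak-to-peak between the stimulated and
the other ROI, in seconds; an onset-based secondary lag can be derived
from the responder threshold crossing but the peak-to-peak value is
primary. "Detectable response" is operationalised as post-stimulus
ΔF/F₀ exceeding baseline mean + k·σ (default k = 5) for ≥ 3 consecutive
frames; a single-frame excursion at exactly k·σ is a non-responder.
On 1000 simulated null traces this rule fires in < 1% of cases.

Kymographs sample a polyline at 1-pixel arc steps; each column is the
mean over an odd-width perpendicular band (default 15 pixels ≈ 2.5 µm
at 0.166 µm/pixel), bilinear interpolation, time down the rows.

The Ca²⁺ initiation site is located from the first post-stimulus frame
in which any contiguous pixel cluster inside the ROI exceeds the
per-pixel baseline mean + k·σ: the site is the intensity-weighted
centroid of the cluster's ≥ 75%-of-maximum core. The core restriction
matters when initiation sits at the ROI boundary — the wavefront disk
is clipped to a half-disk there and a plain centroid is biased inward
by ~0.4 µm at the default wave speed, while the brightest
(earliest-activated) core stays at the origin; both boundary-seeded and
interior-seeded simulations recover the seed within one pixel. With
several simultaneous clusters the largest wins and the result is
flagged ambiguous.

The paired t-test helper wraps the standard two-sided paired Student's
t (n − 1 df) with documented degenerate conventions: identical samples
→ t = 0, p = 1; nonzero constant difference → t = ±∞, p = 0, flagged.
Its type-I error at α = 0.05 is verified to 0.05 ± 0.01 over 10⁴ null
replicates.

### Synthetic Ca²⁺ movies

Each cell's response follows a rise–decay kernel scaled by its true
peak ΔF/F₀ on a constant baseline: half-cosine rise (cell-level rise
time 5 s) to exactly 1, then exponential decay (τ = 20 s). Published
traces constrain the shape only qualitatively; both constants are
configurable. The stimulated cell rises uniformly (the uncaging spot
fills it); in responders the activation front spreads from the
initiation point at a constant wave speed (default 10 µm/s — a typical
intracellular Ca²⁺ wave scale), while every pixel reaches its peak at
the cell's common peak time, later-activating pixels rising faster.
This common-peak construction is what makes the generator's lag an
exact truth for the peak-to-peak estimator while still encoding the
initiation geometry in the onsets; a model in which each pixel ran the
identical kernel shifted by its onset would smear the ROI-mean peak by
up to the intracellular spread time (~0.8 s), which is physics the
published traces do not resolve either way. No reaction–diffusion
model is implied. Nanotube pixels between connected cells carry
baseline fluorescence but no response. Non-connected cells have true
peak 0 by construction.

## Transport velocimetry

Detection: local maxima of the scale-normalised negative
Laplacian-of-Gaussian response, gated at 5 robust noise s.d. (1.4826 ×
MAD) and at 10⁻³ of the global response maximum (the relative floor
silences the flat-background plateaus of noise-free images), plateaus
collapsed to one detection, then per-axis quadratic sub-pixel
refinement (< 0.1 px error on clean spots).

Linking: per frame-pair Hungarian assignment where each active track
bids with the distance from its constant-velocity prediction (last
position plus last step), gated at max_disp × (gap + 1) from the last
observed position; gaps up to max_gap (default 2) frames are bridged.
The velocity term is what keeps identities through crossings — pure
nearest-neighbour assignment resolves same-position crossings at
chance, with prediction ≥ 95% of simulated crossings link correctly.
max_disp defaults to 6 px ≈ 3× the per-frame displacement of a
5 µm/min particle at the default calibration.

Tracks are projected to the nearest point of the reference path (ties
to the earlier segment); points farther than 1 µm are flagged off-path
and a track > 50% off-path is rejected. Mean track velocity is
|s(end) − s(start)| / duration in µm/min — net displacement is robust
to localisation noise, which inflates frame-to-frame speed sums — with
the regression slope of s(t) exported as a secondary estimate and
direction as a separate flag.

Motion classification: straightness = |net Δs| / Σ|Δs| and the MSD
exponent α from a log–log fit of the time-averaged MSD over lags
τ ≤ duration/4, the fit weighted by 1/τ. The weighting reflects that
long-lag TA-MSD points are averages of few, heavily overlapping pairs
whose variance grows steeply with τ; the unweighted fit misclassifies
~12% of 100-point random walks as non-diffusive purely through
estimator spread, the weighted fit ~5%, and the ballistic limit stays
exactly α = 2. Thresholds — directed iff straightness ≥ 0.8 and
α ≥ 1.5; diffusive iff α ≤ 1.2 and straightness < 0.5; else ambiguous —
are operational criteria chosen to leave a deliberate ambiguous band
rather than force borderline tracks into a class.

## Study scenarios and problem sizes

The acceptance studies regenerate each scenario from scratch at the
reported acquisition parameters (105 nm pixels, 45° scan at 0.4 µm
steps; 0.166 µm pixels at 10 fps for Ca²⁺; 1 s frames for transport).
Tube cohorts draw lengths from a zero-truncated normal at the reported
mean ± s.d. (98 tubes cultured, 26 brain-slice); note the truncation
lifts the cultured-cell expectation from 14.85 to ≈ 15.01 µm, well
inside the 2 s.e.m. acceptance band. Each tube is rendered in its own
minimal volume (~4 µm transverse extent) and re-traced. Uncaging
movies run 700 frames of 256 × 320 px with stimulus at frame 110 —
large enough for 8 µm cells, the 100-frame baseline and the 45 s lag;
transport movies run 60–100 frames with one particle per movie, since
each real track comes from a different nanotube. Monte-Carlo checks
use 500 random walks of 100 points (motion class), 1000 null traces
(responder false positives) and 10⁴ null pairs (t-test calibration).

## What the synthetic tests do not show

The phantoms establish that each estimator recovers known truth through
the full image-formation chain at realistic SNR and geometry. They do
not establish performance on real recordings with spatially varying
background, cell movement, focus drift, overlapping tubes, indicator
saturation or bleaching — none of which the generators emulate — and
the seeded tracer assumes a human provides endpoints, as fully
automatic nanotube discovery is out of scope. Axial detection blur is
folded into the single sheet-FWHM Gaussian because a separate axial PSF
is not specified; axial widths are accordingly never reported.
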