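# Methods

This note documents the models, numerical choices and limitations of
`retmap`. The quantities it mentions are the ones computed by the test
suite and `scripts/acceptance.py`; nothing here is asserted beyond what
those runs measure.

## Retinal magnification (`retmap.scale`)

The lateral scale of a retinal image is set by the eye's optics, so
per-subject biometry must enter before any cross-modality comparison.

- **Four-surface model.** A paraxial schematic eye with four refracting
  surfaces (cornea front/back, lens front/back), defaulting to the
  Le Grand full theoretical eye (radii 7.8/6.5/10.2/−6.0 mm, thickness
  0.55/3.05/4.0 mm, indices 1.3771/1.3374/1.42/1.336) with the measured
  axial length substituted and every parameter overridable. The system
  is composed from 2×2 ray-transfer matrices in the reduced-angle
  convention `[y, n·u]`; with system matrix `[[A,B],[C,D]]` the second
  nodal point sits `(1 − A·n')/C` behind the lens back vertex, and
  `RMF = PND·π/180` mm/deg with PND the nodal-point-to-retina distance.
  Because axial length is substituted while power stays fixed, the
  model represents axial ametropia — the standard simplification when
  refraction is not individually modeled.
- **Reduced model.** Bennett's closed form `0.01306·(AL − 1.82)`
  serves as an independent cross-check; the two models agree to ~1% at
  typical geometry and the matrix trace is verified against a
  separately coded surface-by-surface ray trace to 1e−9 mm/deg.
- **Contact-lens correction.** For imaging through a soft contact lens
  the RMF is multiplied by the chief-ray magnification of the lens+eye
  system relative to the bare eye: a thin lens of power K at distance d
  from the eye's entrance pupil scales the chief-ray angle by
  `1/(1 − K·d)`. The entrance pupil is placed 3.05 mm behind the
  cornea by default (the schematic anterior-chamber depth) and the
  lens sits on the cornea (`effective_distance = 0`); both are
  configurable. For ±5 D this gives corrections of ≈0.985/1.015.

## Desinusoiding (`retmap.desinusoid`)

Pixels are clocked uniformly in time while the resonant scanner moves
sinusoidally, so column position follows
`p(i) ∝ sin(θ·(2i/(W−1) − 1 − φ))`, with θ the half-sweep angle
actually used (θ→0 is a linear scan) and φ a centering offset. Line
centers of a Ronchi-ruling image are detected on the column-mean
profile by NCC with a Gaussian line template plus parabolic subpixel
refinement, and (θ, φ) are fitted by nonlinear least squares using the
equal-spacing constraint of the ruling — the physical line period and
distance are accepted for provenance but do not affect the shape of
the correction. The LUT maps output columns (uniform in field
position) to fractional source columns; monotonicity is asserted on
every fit. Images are resampled per row with cubic spline
interpolation (linear fallback); an identity LUT short-circuits to a
bit-exact copy. Resampling is intentionally not idempotent. Output
width equals input width; the µm/px of the corrected image should be
recomputed via the RMF. Slow-axis distortion is out of scope.

## Strip registration (`retmap.register`)

Offsets follow the convention `frame(x, y) ≈ reference(x+dx, y+dy)`.
Whole-frame ranking uses zero-mean NCC (constant frames are flagged
−∞). Strips default to 32 rows with 50% overlap; each strip is matched
by exhaustive NCC over integer shifts within the search radius and
refined by parabolic interpolation of the correlation surface — except
when the peak is exactly 1 (a perfect match), where the parabola would
only add bias, so the integer shift is kept. Strips with peak NCC
below 0.5 are rejected (blink / tear-film dropout) and excluded from
averaging. Accepted strips are shifted (bilinear by default, Fourier
optional) and accumulated with a coverage map; uncovered pixels are
NaN. The mean of identical frames is exact up to floating-point
summation (a few ulps). Rotation/torsion and intra-strip shear are not
modeled.

## Montage and the common frame (`retmap.montage`)

- Pixel coordinates are 0-based, pixel-center, x right / y down; the
  common frame is in µm.
- Landmark alignment fits a similarity transform by the Umeyama closed
  form (affine by linear least squares when anisotropy demands it) in
  µm space, so the fit absorbs only residual rotation/translation/small
  scale after RMF scaling; residual RMS is reported and verified
  against the normal equations.
- Montage placement starts from fixation coordinates × RMF and refines
  each tile against the partially built canvas by NCC within a search
  radius; overlaps are feathered linearly (border distance / 10 px).
  Tiles without usable overlap are placed by fixation alone and
  flagged with a NaN residual.
- The foveal center is marked on the OCT en-face layer and stored in
  the common frame; eccentricity is `mm = ‖p − fovea‖/1000`,
  `deg = mm/RMF`, with the meridian from 90° sectors. Laterality: with
  x increasing rightward, +x is temporal retina for OS and nasal for
  OD; importers may flip images (`anatomical_x`) to make +x temporal
  for both eyes. −y (image up) is superior.

## Mosaic metrics (`retmap.mosaic`)

- **Detection** is a matched band-pass: Gaussian smoothing at
  0.15×expected spacing minus a 3× wider Gaussian, regional maxima
  above 30% of the dynamic range, and greedy minimum-separation
  suppression at 0.5×spacing (brighter peak wins; raster order breaks
  ties). The split-detection channel is first collapsed from its
  signed horizontal edge-pair profile to a centered spot by a
  horizontal derivative-of-Gaussian filter, thresholded against the
  positive peak because the response is signed. Expected spacing below
  2 px is rejected as unresolvable.
- **Edits** (add/remove lists) replace the interactive marking step;
  removals match the nearest center within 3 px, unmatched removals
  are logged and skipped, and the edit log rides with the mosaic.
- **Voronoi metrics**: the tessellation uses all centers within the
  ROI plus a guard margin of 2×expected spacing so edge cells have
  true neighbors; a cell is *bounded* iff its polygon is contained in
  the ROI (boundary contact allowed). `density·Σareas = n_bounded`
  holds exactly by construction; on lattices the analytic density is
  recovered to machine precision. Spacing defaults to
  nearest-neighbor distance of bounded centers (mean Voronoi-neighbor
  distance via `spacing="voronoi"`). ROIs default to 50 µm within
  0.3 mm of the fovea and 100 µm beyond.
- **Dark cones**: split and confocal centers are matched greedily,
  closest pairs first, within a match radius in the common frame;
  unmatched split-detection cells are candidate non-waveguiding cones.

## OCT layers (`retmap.octlayers`)

Boundaries ILM, OPL (posterior), EZ (center) and RPE-BrM (posterior)
are segmented per B-scan in three steps: (1) global estimates on the
lateral-mean A-scan profile (first strong positive gradient, strongest
negative gradient below the brightest band, etc.); (2) per-column
tracking of each boundary's feature extremum inside a window clamped
at midpoints to adjacent boundaries, on a heavily laterally smoothed
image (6×) for speckle robustness — the EZ is located per column as
the most anterior prominent intensity ridge between the OPL and
RPE-BrM tracks, because the RPE band itself is brighter; (3) a 1-D
active contour per boundary (external force = normalized axial
derivative of the gradient/ridge feature, implicit second-difference
smoothing with weight 0.5, 60 iterations) with optional seed polylines
re-imposed as hard constraints every iteration. The ordering
ILM ≤ OPL ≤ EZ ≤ RPE-BrM is enforced by sorting wherever all four are
defined. Positions stay fractional; `RT = (RPE-BrM − ILM)·axial` and
`ORL = (RPE-BrM − OPL)·axial` (defaults 3.5 µm/px axial, 14 µm/px
lateral). Thickness at nasal offsets projects the displaced foveal
center through the en-face transform and averages a 10-A-scan window
in-B-scan (partial windows flagged). On speckle phantoms (SNR 5,
±4 px boundary undulation) the per-boundary MAE is ~0.1 px and
thickness errors are well under one axial pixel.

## Statistics (`retmap.stats`)

- **z-scores** use the nearest normative row within 0.15 mm (no
  interpolation by default); abnormal iff z < −2, strictly, so a value
  at exactly −2 SD is still "normal". Age matching is delegated to
  normative-table construction.
- **Wilcoxon rank-sum** uses midranks; exact p by complete enumeration
  of all C(n+m, n) rank assignments (feasible to combined n = 20, PMF
  cached per rank multiset), two-sided as the null probability of a
  rank sum at least as far from its mean as observed. The normal
  approximation is continuity-corrected with tie-corrected variance.
  Under the null (n = m = 8) the exact test's measured type-I error at
  α = 0.05 is ≈0.05.
- **ICC(A,1)**: two-way ANOVA mean squares with
  `ICC = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)` and the
  McGraw–Wong F-based 95% CI; verified against a brute-force
  sums-of-squares oracle and an independent implementation.

## Phantom generators (`retmap.synthetic`)

One integer seed drives everything; each sub-generator forks a named
stream (seed + CRC32 of the name), so e.g. changing the frame count
does not change the mosaic. Defaults mirror the targeted acquisition:
150-frame sequences, 3.5/14 µm-per-px OCT sampling, cone densities
spanning the healthy foveal range (~105,000–164,000 cells/mm²) down to
the severely reduced mosaics seen in disease (~1,000 cells/mm²), RT
and ORL magnitudes of ~250–335 and ~100–147 µm.

- Mosaics are jittered hexagonal lattices (Gaussian jitter,
  10% of spacing by default); radial density profiles are realized by
  an area-preserving radial warp (exact radially, approximate
  tangentially for steep gradients). A seeded fraction of cells is
  labeled *dark* and omitted from the confocal rendering only.
- Renders: confocal = Gaussian spots; split-detection = signed
  horizontal derivative-of-Gaussian per cell; dark-field = broad
  overlapping blobs. Noise is Poisson shot noise plus Gaussian read
  noise scaled so the peak-signal-to-noise equals the spec SNR.
  Centers are splatted at the nearest pixel, so rendered ground truth
  carries ≤0.5 px quantization — relevant when judging subpixel
  localization, not density.
- Frame sequences apply a per-frame global translation plus a
  row-dependent sinusoidal horizontal shift (raster-time eye drift) and
  return the exact per-row waveforms as ground truth.
- OCT B-scans are soft-edged intensity bands (tanh transitions,
  half-width 1.2 px so gradients peak on-boundary) with a Gaussian EZ
  ridge and a bright RPE band, multiplied by gamma-distributed speckle
  of SD 1/SNR.
- Ruling images render equally spaced Gaussian lines through the same
  scan model the desinusoid module fits — the generators and the
  fitter share one parameterization deliberately, so the fit is tested
  for parameter recovery, while LUT round-trip error is judged against
  the analytically inverted map.

What the phantoms do **not** emulate: wave-optical AOSLO image
formation (confocal speckle statistics, PSF asymmetries), torsional
eye motion, vascular shadowing, pathology morphology beyond dark
cones, and OCT vendor processing. Passing phantom tests therefore
demonstrates the correctness of the numerics, not clinical-grade
robustness on patient images.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small instances —
~250² px AOSLO fields, 2–5 B-scan volumes of 256×96–128, 150-frame
sequences probed on a 30-frame subset, 10–50 Monte-Carlo seeds — which
keep the full suite under a minute while leaving every estimator in
its asymptotic regime. The end-to-end session pipeline is byte-identical
across re-runs for a fixed seed; µm quantities in CSVs are serialized
at 3 decimals to keep text outputs diff-stable.

## Known limitations

- The four-surface eye is paraxial: no chromatic dispersion, no
  off-axis (wide-field) magnification variation.
- Montage refinement is translation-only against the growing canvas;
  a global bundle adjustment over the placement graph is not
  implemented.
- Strip registration estimates horizontal/vertical translation per
  strip; within-strip shear and rotation are unmodeled.
- The OCT segmenter assumes the four-band reflectivity ordering of a
  structurally intact retina; it flags but does not model boundary
  loss inside atrophic lesions.
- `wilcoxon_rank_sum(mode="exact")` is limited to combined n ≤ 20 by
  enumeration cost; beyond that use the normal approximation.
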