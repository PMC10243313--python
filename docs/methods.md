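# Methods

This note records the models, conventions and numerical choices behind
`vaudit`, in the order data flows through an audit.

## Coordinate and dose conventions

All geometry lives in the DICOM patient coordinate system, millimetres,
voxel-centre convention, axis-aligned grids only (the audit phantoms are
scanned axis-aligned; oblique orientations are rejected, not silently
resampled).  Dose is absolute Gy for the single delivered fraction of the
20 Gy / 10-fraction audit prescription — nominally a 2 Gy target plateau.
There is deliberately no normalisation step anywhere: "no dataset
scaling" is enforced structurally, not as an option.

Interpolation is bilinear/trilinear throughout.  Higher-order schemes
were excluded on purpose: linear interpolation is exact on linear dose
fields, which gives every resampling and sampling operation an analytic
oracle (`extract_plane`, `resample_plane` and `sample_at_detectors` are
all tested against globally linear fields at 1e-9).

## Gamma engine

Global gamma with the measured distribution as the *reference* (the set
of scored points) and the planned one as the *evaluated* distribution
(the one searched).  This assignment is fixed across film (dense pixel
grid) and arrays (sparse diodes): the audit asks "does each measurement
agree with the plan", and it keeps the denominator and threshold
semantics identical for both workflows.

* **Denominator** — `fixed_dose` (2 Gy, film preset) or
  `max_of_evaluated` (array preset: the maximum of the planned
  distribution actually being compared against, e.g. the unwrapped
  cylinder plane for ArcCHECK, the two extracted planes pooled for
  Delta4).
* **Threshold** — applied to the measured dose, as a percentage of the
  same denominator as the dose criterion.  Points below threshold carry
  NaN in the gamma map and are excluded from the passing rate.
* **Search** — candidate positions on a square lattice of pitch Δd/50,
  radius capped at 3·Δd.  `gamma_map` visits candidates sorted by
  distance and stops as soon as the pure distance term exceeds the
  current minimum; with sorted candidates this prune is lossless, and the
  cost per point scales with its gamma value, so well-matched data is
  scored almost instantly.  `gamma_bruteforce` scans the identical
  lattice exhaustively with no ordering, pruning or early exit, and
  serves as the independent oracle in the tests.  A pitch of Δd/10 with
  local refinement was evaluated and rejected: it leaves ~2% of points in
  steep-gradient regions short of the refined minimum.  Both kernels are
  numba-compiled.
* **Ties and boundaries** — equal-value candidates resolve to the first
  found (the minimum value is order-independent); candidates outside the
  evaluated support are skipped; a reference point whose entire search
  window misses the support gets γ = ∞ and fails.  γ ≤ 1 and
  rate ≥ tolerance are both inclusive comparisons, so a rate of exactly
  90.0% under the film preset passes.
* **Degenerate inputs** — an empty evaluated distribution, an all-zero
  plan under `max_of_evaluated`, or no reference point above threshold
  each raise a specific error rather than returning a vacuous 100%.

## Film pipeline

The scan is a single composite image: irradiated film plus at least three
calibration subfilms (0, 0.5, 2 Gy), each exposed under reference
conditions.  Processing steps and their reasoning:

1. **Red channel, untouched.**  Radiochromic film is read on the red
   channel where sensitivity below ~3 Gy is highest; no smoothing or
   filtering is applied to measurement data, ever (the output is
   bit-identical to the channel, and a test asserts that).
2. **Optical density** OD = −log10(PV/65535) with pixel values clipped
   to ≥ 1.  The white level is the scanner's 16-bit full scale; its exact
   value cancels in the next step.
3. **Non-uniformity correction.**  Net OD subtracts the unset
   (unexposed) film's OD — any additive scanner-response field present in
   both scans cancels exactly (tested to 1e-12).  With a full unset scan
   the correction is a 2-D map, median-filtered 5×5 (the only filtered
   object in the pipeline, and it is a correction map, not data).
   Without one, the scalar mean OD of the 0 Gy subfilm is used; the
   report records which path ran.  Negative net OD is sub-base noise:
   clipped to zero and counted in a warning.
4. **Calibration.**  Dose against net OD is fitted by least squares with
   the polynomial constrained through the origin — the 0 Gy subfilm pins
   D(0) = 0 — and degree d = min(3, n_points − 1).  A third-degree fit
   through three subfilms is underdetermined; the constraint scheme makes
   the canonical {0, 0.5, 2 Gy} set a well-posed quadratic and lets five
   or more points use the full cubic, degrading gracefully instead of
   silently overfitting.  A fitted curve that is not strictly increasing
   over the calibrated OD range cannot be inverted and aborts the audit.
   OD above the fitted range is extrapolated with a warning (fiducial
   marks and inter-film gaps legitimately exceed it).
5. **Registration.**  Four ink marks near the film sides, drawn on the
   isocenter cross at delivery, are detected per edge band: threshold =
   max(Otsu, median + 0.1 OD, median + half the band's peak-above-median),
   largest connected blob, intensity-weighted centroid.  The half-peak
   floor matters: target penumbra can reach an edge band, and the marks
   are by construction the densest feature there.  Two comparable blobs
   in one band abort with the side named — an audit guesses nothing.
   The isocenter is the intersection of the left–right and top–bottom
   mark lines; the rotation is the mean angular deviation of those lines
   from the image axes (|rotation| > 10° is rejected as implausible).
   The dose plane is then resampled (bilinear) onto an isocenter-origin
   grid with the rotation undone; pixels leaving the film support are
   marked invalid and excluded downstream.
6. **Plausibility check.**  The mean measured/planned dose ratio over the
   planned ≥ 90%-of-max region is reported as "calibration-suspect" when
   it deviates more than 5%: a subfilm exposed to the wrong dose rescales
   the entire converted film, and this ratio names that cause where the
   passing rate alone could not.

The film's plane (axial or coronal) is declared in the audit
configuration, mirroring the two phantom setups; it is not auto-detected.

## Array geometries

* **ArcCHECK** — diodes on a helix wound on a cylinder: 10 mm of arc per
  diode along the helix, 10 mm axial pitch per turn.  Radius 104 mm and
  length 210 mm are vendor constants, overridable in configuration and
  recorded in every report; the default build has 1373 diodes.  Analysis
  happens on the unwrapped surface (arc length u = r·θ, axial z), an
  isometry of the cylinder except across the seam; θ = 0 is posterior,
  z = 0 the isocenter plane.  The planned dose is sampled on the same
  unwrapped lattice (1 mm pitch), extended one search-cap past the seam
  on both sides so gamma searches near u = 0 see both neighbours.
* **Delta4** — two orthogonal diode boards through the isocenter,
  modelled as the coronal and sagittal planes: 5 mm pitch where both
  in-plane coordinates are within ±30 mm (central 60×60 mm², boundary
  inclusive), 10 mm elsewhere out to ±100 mm.  Diodes on the shared
  z-axis line belong to the coronal plane only, so the partition is
  exhaustive and disjoint.  Gamma runs per plane against the matching
  planned plane; the passing rate is pooled over all evaluated diodes of
  both planes with one denominator per dataset (the maximum of both
  planned planes), since the credentialing decision is per submission,
  not per board.

Measured doses travel in a deliberately minimal text dialect owned by
this package (`#`-prefixed `key: value` headers including `device`, then
`id<TAB>dose_gy` lines).  Vendor-native exports vary too much to parse
generically; converters are explicitly out of scope.

## Synthetic data generator

The generator emulates the audit's study conditions, not a treatment
planning system:

* **Planned field** — analytic: a 2 Gy plateau on a C-shaped region
  (annulus 10–30 mm, 270° arc, 50 mm axial slab) with a 5 mm Gaussian
  penumbra and a weak 60 mm scatter tail, plus a transit-dose bath
  peaking near the phantom surface (0.8 Gy at r = 104 mm, decaying with
  45 mm depth constant) so the ArcCHECK cylinder sees the realistic
  ~1 Gy level.  The built field respects the audit plan constraints —
  global maximum 2.15 Gy (< 110% of 2 Gy), avoidance-core centre 0.69 Gy
  (< 60%) — and is written as standards-conformant RT Dose / RT Plan by a
  writer independent of the package's own readers.
* **Film forward model** — PV = 65535·10^−(OD_base + g + curve⁻¹(D)),
  with film-base OD 0.05, a smooth additive scanner field g (2% OD
  peak-to-peak, also present in the unset scan so the correction is
  honest), the true response inverted by dense monotone interpolation,
  0.5% multiplicative Gaussian pixel noise, and Gaussian ink marks
  (σ = 2 px, +1.5 OD) on the isocenter cross.  The true response is the
  gently superlinear cubic D = 3.0x + 1.0x² + 0.5x³ (≈ 0.54 net OD at
  2 Gy), the shape of red-channel radiochromic response below ~3 Gy — a
  shape the three-subfilm constrained quadratic approximates to
  ~0.007 Gy, so calibration-model error stays well under the pipeline's
  1.5%-of-2-Gy recovery budget.  Film size 100 mm at 150 dpi keeps the
  fiducial edge bands clear of the 30 mm-radius target's penumbra.
* **Detector measurements** — the planned field sampled at diode
  positions with 0.005 Gy additive Gaussian noise.
* **Planted errors** — one per scenario: `subfilm_overdose` (the 2 Gy
  patch truly at e.g. 2.17 or 2.293 Gy while the layout still declares
  2 Gy), `dose_scale` (global output error), `shift` (setup error),
  `rotation` and `iso_offset` (film placement on the scanner).  All
  writers draw from named seeded generators; a fixed seed reproduces
  byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: optimiser-generated modulation texture,
film artefacts beyond multiplicative grain (scratches, Newton rings,
lateral scanner response beyond an additive OD field), angular dose-rate
dependence of diodes, and measurement-device calibration drift.  The
tests establish that the *analysis* is correct and sensitive to the
planted error classes, not that any institution's delivery is.

## Problem sizes and runtimes

Defaults were chosen so a complete audit round-trip is interactive on one
CPU: a 93³ planned grid at 2.5 mm pitch, a 591² px film at 150 dpi
(~3·10⁵ gamma reference points), 1373/1095 diodes for the arrays, and
41² fields for the 50-field search-vs-oracle comparison.  An error-free
film audit takes ~2 s; a grossly discrepant one (the miscalibrated-
subfilm scenario) ~30 s, because the gamma search cost grows with the
disagreement it measures.

## Known limitations

* Single-channel (red) dosimetry only; no triple-channel correction.
* The unset-film question (2-D map vs scalar, separate sheet vs 0 Gy
  subfilm) is genuinely ambiguous in practice; both paths are supported
  and logged, the 2-D map being the default when a scan is supplied.
* Gamma is 2-D per plane; no volumetric search across planes.
* The verdict is exactly the passing rate against the tolerance —
  warnings inform the reviewer but never alter it, which is a design
  stance, not an oversight.
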