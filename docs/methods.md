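# Methods

## Gradient-beam calibration

Each gradient beam is calibrated from replicated beam-profiler line scans
taken along its gradient axis: tuples (position μm, irradiance mW/cm²,
replicate id), positions strictly increasing within a scan.  The model is a
1-D polynomial E(u) = Σₖ cₖ uᵏ fitted by ordinary least squares.  Replicate
scans are pooled as independent observations (a `use_replicate_means`
switch fits per-position means instead; for balanced replicates both give
the same mean curve).

Numerically, positions are rescaled by max|u| before the Vandermonde matrix
is built, which keeps the design well conditioned up to degree 6 over a
1200 μm axis; coefficients and their covariance are mapped back to the
original scale exactly.  Evaluation uses Horner's nested scheme and is
tested against direct term-by-term summation.

**Degree selection.** The polynomial degree is chosen by the least-squares
AIC, n·ln(RSS/n) + 2k with k = degree + 2 (coefficients plus the noise
variance).  RSS is floored at n·10⁻¹²·mean(y²) so exactly interpolating
fits keep a finite, comparable score; with the floor active, every
interpolating degree shares the same RSS term and the 2k penalty breaks the
tie toward the lowest degree.  Candidate degrees default to {0,…,6}, wide
enough to bracket the quartic (1064 nm) and quadratic (1270 nm) gradients
with headroom.  AICc was considered and rejected: at the calibration sample
sizes in play (hundreds of pooled points) the small-sample correction is
negligible, and plain AIC keeps the score transparent.

**Confidence bands.** The 95% band on the fitted mean curve is the
delta-method (Wald) band: E(u) ± t₁₋α/₂,ₙ₋ₚ · √(v(u)ᵀ Σ̂ v(u)) with
v(u) = (1, u, …, u^d) and Σ̂ the OLS parameter covariance.  This is a band
for the mean curve, not a prediction band for new readings, matching how a
fitted calibration curve's uncertainty is normally displayed.  Saturated
fits (no residual degrees of freedom) have no band and raise.

**The dose map.** Two orthogonal fits — 1064 nm along the image x (column)
axis, 1270 nm along y — compose into a per-pixel map:
dose(col, row) = (E_x(col·p), E_y(row·p)) at pixel size p (default
1.6 μm/px, from a cell diameter of ~5 px ≈ 8 μm under the 4× objective).
Pixels beyond the beam's `field_extent` (default 1200×1200 μm) are flagged
out-of-field and treated downstream as no-laser controls.  The built-in
reference polynomials span ≈208–393 mW/cm² (1064 nm) and ≈53.5–98.2 mW/cm²
(1270 nm) across the field.

## Cell detection, tracking, fold change

Frames are smoothed with a normalized 3×3 Gaussian kernel, σ = 0.85 px —
the largest σ for which the 3×3 truncation still holds ≥99% of the kernel
mass — with replicated edges at the borders.  A pixel is called a cell when
its smoothed intensity is ≥ every smoothed intensity in its centered 5×5
window (clipped at frame borders) and exceeds the threshold.  The ≥
comparison (rather than >) keeps flat-topped spots detectable; within a
plateau of equal maxima inside one window only the first pixel in row-major
order is called, so each spot yields exactly one detection and no two
detections lie within one window radius (Chebyshev distance ≤ 2) of each
other.

The default threshold is median + 5σ̂ of the smoothed frame, with
σ̂ = 1.4826·MAD the normal-consistent robust standard deviation.  Five
background σ puts the Gaussian false-positive rate well below one call per
10⁵ pixels; an absolute threshold can be supplied instead, since real
thresholds are typically set empirically per fluorophore and camera.

Tracking assumes cells do not migrate during the ≤5 min experiment: each
baseline (pre-exposure) detection is matched to at most one detection per
later frame by greedy nearest-neighbor on ascending distance with mutual
exclusivity, accepting matches within 2 px (well under a cell diameter).
Baseline cells missing a match in any analyzed frame are dropped — only
stably positioned cells are analyzed.

Fold change is F(t) = I(t)/I(pre) per cell.  Intensities are read from the
**unfiltered** frames at the called pixel (the smoothed frames serve
detection only), so the filter cannot bias the ratio; a `measure_on`
switch exposes the alternative of measuring on the smoothed frames, and an
optional aperture mean is deliberately not the default because the
single-pixel reading matches how point-like cells are quantified here.
Cells with non-positive baseline intensity are excluded with a logged
reason.  Dose is assigned from the baseline position.

## Dose-response grid and statistics

Cells are binned into a grid of dose rectangles — by default 5 equal-width
bins per wavelength spanning the doses the field actually delivers
(computed exactly from the polynomial's stationary points and endpoints,
not a grid scan), giving 25 groups.  Bins are half-open [lo, hi) with the
topmost edge closed; a dose on an interior edge belongs to the higher bin.
Equal-width binning was chosen over equal-count because the grid's axes are
physical irradiances; occupancy is consequently unequal (the gradient
polynomials are non-linear in position), which the Tukey–Kramer form
handles.

Per group and timepoint the summary is mean fold change, SEM = sd/√n
(undefined below n = 2), and n.  Inference against the no-laser control
(out-of-beam cells) uses one-way fixed-effects ANOVA
(F = MS_between/MS_within on (g−1, N−g) df) followed by Tukey's HSD: for
each pair q = |mᵢ − mⱼ| / √(MS_within/2 · (1/nᵢ + 1/nⱼ)), adjusted p from
the studentized-range distribution with (g, N−g) parameters (scipy's
implementation; the test suite checks it against a direct double-integral
quadrature of the studentized-range CDF to 10⁻⁴).  Groups with n < 2 are
excluded from inference with a warning; α defaults to 0.05.  Replicate
experiments are pooled before testing rather than modeled as a factor,
matching how such single-cell populations are normally combined.

## Synthetic scenes

The generator emulates the acquisition geometry end to end.  Defaults:

| parameter | default | note |
|---|---|---|
| frame | 800×800 px @ 1.6 μm/px | beam field 750×750 px (1200×1200 μm) anchored at the origin |
| cell density | 1 per 40×40 px (≈400 cells) | min pairwise separation 5 px (= detection window) |
| PSF | isotropic Gaussian, σ = 2 px, peak-normalized | amplitude ~ N(2000, 400) counts, floored |
| background / noise | 100 counts; Gaussian read noise sd = 2% of background | optional Poisson shot noise, off by default so oracles stay exact |
| bleaching | 2% per acquisition, uniform across cells | baseline is the first exposure |
| output | 16-bit, quantized and clipped | identical seed ⇒ identical bytes |
| response | fold 0.85 at 1 min inside 250–400 × 55–65 mW/cm², 1.0 outside and at 5 min; between-cell sd 0.10 | the 0.85 effect size is a generator choice, not a measured value |

The frame is slightly larger than the beam so the ~12% out-of-beam margin
supplies the no-laser control population that the comparison stage needs;
cells there are flagged controls with unit mean fold.  Beam-profile scans
are simulated as truth(u)·(1 + ε), ε ~ N(0, 2%), 5 replicates, 61 positions
at 20 μm spacing.

What the generator does **not** model: fluorophore photochemistry and
calcium/ROS kinetics (only the observed fold change is programmed), cell
migration and focus drift, non-uniform background, saturation of real
cameras, and spatially correlated noise.  Passing tests therefore
demonstrate that the pipeline recovers what the forward model puts in —
positions, doses, fold changes, the suppression window — not that the
biological effect sizes are correct.

Ground-truth checks compare recovered group means against the programmed
response *after* the programmed per-acquisition bleach factor, since
bleaching is part of the rendered signal; the remaining background-offset
bias of the single-pixel ratio is ≈0.001 at the default amplitudes, far
below any group SEM.

## Problem sizes and determinism

The default full-pipeline check pools two independent synthetic runs
(≈800 cells), which gives every dose group enough members (mostly n ≥ 10)
for stable means while a complete run stays around a few seconds.  All
randomness flows through `numpy.random.default_rng` seeded from a single
integer; the pipeline writes a run log (config hash, versions, seed) so
every output is regenerable from config + seed alone.

## Known limitations

- Detection treats cells as point maxima; touching or overlapping cells
  within one 5×5 window merge into a single call.
- No drift/registration correction; a stage shift larger than the 2 px
  tolerance silently drops cells rather than re-registering them.
- The irradiance map assumes the gradients are exactly axis-aligned and
  separable; a rotated or sheared beam would need a 2-D calibration.
- Equal-width default bin edges depend on the fitted dose ranges, so two
  calibrations yield directly comparable grids only if their ranges match.
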