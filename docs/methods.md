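# Methods

## Measurement model

A dark-grown seedling is annotated with three landmarks (all in
(row, col) image coordinates, 0-based, pixel centers at integers): the
hypocotyl axis as a proximal→distal point pair, the cotyledon line as a
hook-side→tip point pair, and the hook vertex on the concave tissue
edge. From these the package computes:

**Hook angle.** The angle between the oriented hypocotyl direction and
the oriented cotyledon direction, via the arccosine of their dot
product, so the result lies in [0, 180]°. Convention: 180° = fully
closed hook (cotyledon line antiparallel to the hypocotyl), 0° = fully
open. The quantity is invariant under translation, rotation and uniform
scaling of the landmarks. Landmarking is manual (or generator-provided);
automatic seedling segmentation is out of scope.

**Bisector chord.** The staining gradient is read along the bisector of
the hook angle. The bisector line at the vertex is computed as the polar
mean (normalized vector sum) of the distally oriented hypocotyl
direction and the *reversed* cotyledon direction; for a hook bending
along a circular arc this orientation is exactly the outward radial at
mid-arc, i.e. it points from the concave interior outward through the
tissue. (Bisecting the organ rays themselves gives the same line with
the opposite orientation, pointing into the hook's interior.) The
bisector is undefined at 0° and the chord construction is only offered
for interior angles in (0, 180); hooks curling past 180° are not
modeled. `tissue_chord` walks the ray in 0.5 px steps with bilinear
interpolation, takes the first sample at or above a threshold as the
concave end and the last sample of that contiguous run as the convex
end, then refines both ends to the subpixel threshold crossing so chord
length is not quantized to the step. The default `"auto"` threshold is
the midpoint between the minimum and maximum sampled value along the
ray; a zero-contrast ray (no tissue at all) is reported as an error
rather than thresholded. Both the threshold and the step are
configurable.

**Profile.** Photographs are converted to a scalar signal with fixed
luminance weights (0.299, 0.587, 0.114). GUS staining is dark on a
bright background, so the default polarity `stain_dark` inverts the
gray value (white level − luminance); `stain_bright` passes it through
(synthetic images are already signal-valued). Whether a given data set's
gray values need inversion is recorded in the run log rather than
guessed. The signal is sampled along the chord at equal arc-length
steps (single-pixel line by default; an averaging band of k
perpendicular offsets is available), positions are mapped affinely onto
s ∈ [0, 1] (0 = concave, 1 = convex) and values are linearly resampled
onto a uniform grid of `n_points` (default 101; endpoint values
preserved exactly). No background subtraction is applied by default and
values are never rescaled — units stay the image's native arbitrary
units. Ensembles on a common grid are summarized by the pointwise mean
and sample SD (ddof = 1; SD defined as 0 for n = 1).

**Summaries.** Total integrated intensity is the trapezoidal integral
of the profile over [0, 1]. The ARDI is the smallest s* at which the
cumulative trapezoidal integral reaches half the total, with linear
interpolation of the cumulative inside the bracketing grid interval;
zero-signal plateaus at exactly half-mass resolve to the leftmost
point. ARDI is scale-invariant (to floating-point roundoff) and maps
profile reversal to 1 − s* within one grid step.

## Statistics

One-way comparisons use the standard F-test plus Tukey's HSD from the
studentized-range distribution (Tukey–Kramer for unequal n). Two-way
analysis (genotype × treatment, with interaction) requires a balanced
design with ≥ 2 observations per cell — the ambiguity between Type
I/II/III sums of squares does not arise on balanced data — and applies
Tukey HSD over all cell means. Pairwise decisions at α (default 0.05)
are condensed into a compact letter display by the insert-and-absorb
algorithm: every significant pair splits the columns containing both
members, subsets are absorbed, and letters are assigned in group order;
groups share a letter iff their difference is not significant.

Dose-response strength is the two-point slope of the mean hook angle
per decade of inhibitor concentration,
(mean(c_high) − mean(c_low)) / (log10 c_high − log10 c_low), per
genotype and day. The log abscissa reflects the geometric spacing of
tested doses; the mock treatment (c = 0) cannot sit on a log axis and
is rejected from slope computation. Sensitivity is summarized
separately as the minimum effective concentration: the smallest dose
whose Tukey comparison against mock is significant at α.

## Synthetic generator

The generator emulates the study conditions so that every stage is
testable without photographs. A seedling is drawn as a straight
vertical hypocotyl joined to a circular-arc hook of interior angle
equal to the true hook angle, ending in a short cotyledon stub; tissue
width is 2·h with h = 20 px by default. Within the hook, signal varies
only across the cross-section: at relative depth u (0 = concave edge,
1 = convex edge) it equals B + S0·e^{−λu}. The exponential-plus-
baseline family is the simplest monotone gradient with a closed-form
cumulative, which makes the true ARDI available analytically (root of
the half-mass equation, located by Brent's method to ≤ 1e−9). Defaults:
S0 = 100, B = 150, background 10, pixel noise SD 5 (5% of S0, additive
Gaussian, clipped to the representable range), image 220 × 220. The
baseline exceeding zero mirrors real GUS curves, whose convex-side gray
values stay well above the unstained background; it also keeps the
convex tissue edge ≈ 5 noise-SD above the midpoint auto-threshold, so
chord detection is robust at the default noise level. Tissue edges are
antialiased with a ~1 px linear blend so bilinear sampling behaves like
the continuous field. Images written to disk are quantized to 8- or
16-bit grayscale PNG/TIFF, whichever fits the dynamic range.

Scenario presets vary only the gradient and hook shape: `wt_like`
(λ = 3, well-formed hooks ≈ 160°), `hyl1_like` (λ = 0.3, flattened
gradient, more open hooks), `concave_shifted` (λ = 6) and
`flat_gradient` (λ = 0, true ARDI exactly 0.5). Per-seedling hook angle
and half-width jitter are Gaussian with clipping to valid ranges.
Random-number consumption order is fixed and documented in the module
docstring so seeds are portable.

What the generator does **not** emulate: photographic illumination
gradients, color (images are single-channel signal fields), cotyledon
staining, along-arc signal variation, seedling-shape irregularity, or
hooks curling past 180°. Passing closure tests therefore demonstrates
correctness of the measurement chain, not robustness to photography
artifacts; for real images the polarity, threshold and background
options exist precisely because those factors vary.

## Numerical choices and validation scale

- Chord sampling step 0.5 px; profile grid 101 points; both
  configurable. At the default tissue diameter (40 px) the end-to-end
  profile reproduces the generating field to within ~0.5% of S0 outside
  a ~2 px edge-blend zone at each chord end, chord endpoints land
  within ~0.6 px of the analytic edges, and measured ARDI is within
  ~0.004 of truth on noise-free renders.
- ARDI on a 101-point grid agrees with a 10⁶-point brute-force
  integration to < 1e−3 across the baseline+exponential family
  (λ ≤ 5).
- Validation experiments run at deliberately desk-scale sizes — 30
  seedlings per scenario for the closure/discrimination experiment, 500
  null simulations for ANOVA calibration, n = 30 per group for slope
  recovery — chosen to give stable estimates (binomial SE ≈ 0.01 on the
  type-I rate; slope SE ≈ 1.3 deg/decade) while keeping the whole suite
  fast on a single CPU.
- CSV outputs use a fixed column order and `%.10g` floats; run logs
  contain the config digest but no timestamps, so identical
  configurations produce byte-identical outputs.
- Degenerate inputs fail loudly with typed errors: zero-signal profiles
  (ARDI undefined), fully open hooks (bisector undefined), zero-contrast
  rays, tissue runs truncated by the image border, unbalanced two-way
  designs (the offending cell is named), and mock concentrations on the
  log dose axis.

## Known limitations

- Landmark quality bounds everything downstream; the package does not
  detect landmarks from pixels.
- The two-point dose-response slope is not a dose-response curve fit; a
  4PL model is deliberately out of scope.
- Replicate structure is pooled, matching the upstream experimental
  design; no mixed-effects modeling of biological replicates.
- SEM is not reported directly, but every statistical output carries
  both n and SD, from which SEM per pooled sample follows.
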