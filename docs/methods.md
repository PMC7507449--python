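# Methods notes

## Model and assumptions

The pipeline assumes axial T1-weighted slices in which muscle tissue and
adipose tissue form two separable intensity modes after bias-field
correction, with adipose the brighter mode.  Tissue membership is decided
purely per pixel against a slice-wise threshold; no spatial regularisation,
atlas prior, or partial-volume model is applied.  Anatomy enters only
through the traced outlines (13 thigh muscles, the deep fascia, the femur),
which are treated as given inputs — tracing is out of scope.

Slices are analysed independently.  The inter-slice distance (24 mm
center-to-center at the default acquisition: 12 mm slice thickness plus
12 mm gap) is large relative to the in-plane pixel (1.40625 mm), so a 3-D
bias-field or segmentation model would couple nearly independent data;
per-slice processing is both closer to the workflow the pipeline mirrors
and easier to validate.  The slice spacing used for volume integration is a
configurable field of `AcquisitionGeometry` because "inter-slice distance"
is ambiguous between gap and center-to-center conventions; the default
treats it as a gap.

## Bias-field correction

The estimator is the classic histogram-sharpening scheme: log-transform
signal pixels, Wiener-deconvolve a Gaussian from their histogram, take the
conditional expectation E[u | v] of the sharpened distribution, smooth the
residual with a tensor-product cubic B-spline, accumulate, repeat.

Parameters (all exposed on `N3Params`):

| parameter | default | units | role |
|---|---|---|---|
| `end_tolerance` | 1e-4 | — | stop when CV of the between-iteration field ratio drops below it |
| `max_iterations` | 100 | — | iteration cap |
| `signal_threshold` | 1 | intensity | pixels below it are excluded from fitting |
| `field_distance_mm` | 25 | mm | spline control-point spacing |
| `subsampling_factor` | 4 | — | stride of pixels used for fitting |
| `kernel_fwhm` | 0.15 | log-intensity | width of the deconvolved Gaussian |
| `wiener_noise` | 0.01 | — | Wiener regularisation constant |
| `n_bins` | 200 | — | histogram resolution |

Numerical choices that matter:

* **Histogram range padding.** The histogram range is padded by 4 kernel
  sigmas on both sides.  Without padding, an intensity mode sitting at the
  extreme of the sample range (the femur, the brightest fat) is truncated
  at the boundary, which biases E[u | v] near the edges and leaves
  mode-dependent offsets in the recovered field (observed as a ~5 % error
  on the femur before the fix; < 0.5 % after).
* **Fitting mask.** `correct_stack` restricts fitting to the largest
  connected supra-threshold component (the limb).  With additive noise,
  air pixels can exceed the signal threshold; treating their near-zero
  intensities as a genuine tissue mode destabilises the iteration.
  `estimate_bias_field` itself accepts any mask, defaulting to the plain
  threshold rule.
* **Smoother.** A least-squares tensor cubic spline with knots every
  `field_distance_mm / pixel spacing` pixels.  Knot cells outside the limb
  carry no data and make the system rank deficient; the minimal-norm
  solution is accepted, and the accumulated log-field is clamped to ±3
  before exponentiation so the extrapolated field stays positive and
  bounded.  Degenerate geometries (tiny test slices) fall back to a global
  cubic polynomial surface.
* **Normalisation.** Each increment is mean-centred over the mask and the
  final field is scaled to mean 1 over the mask, so correction preserves
  mean signal intensity (`apply_correction` additionally rescales exactly).

On noiseless phantoms with a second-order polynomial field the estimate
correlates > 0.997 with the truth (RMS relative error ≈ 0.4 %).  At SNR 20
the estimate partially absorbs noise structure — the corrected image is as
uniform as with the true field, but the field itself is not interpretable
pointwise; downstream classification is unaffected because it compares
corrected intensities to a threshold derived from the same image.

## Threshold isolation

The pooled ROI histogram uses 256 bins over the sample range (padded 2 %
per side so a spike mode at the range extreme still registers as an
interior peak) and Gaussian smoothing with sigma = 2 bins.  Modes must rise
with prominence at least 0.2 of the smoothed maximum — with balanced
muscle/SAT ROI pooling both genuine modes easily qualify, while sparse-
histogram sampling wiggle does not.  A sample without two such modes raises
`BimodalityError` rather than guessing.

The threshold ("base of the first peak") is the minimum of the smoothed
valley between the first two modes, with two refinements:

* when the valley floor is a flat plateau (zero counts between
  well-separated modes) its **midpoint** is used, which coincides with the
  mixture-density minimum for symmetric separation;
* otherwise the vertex of a quadratic fitted over ±8 bins around the
  argmin gives sub-bin precision.  Against brute-force density minima of
  two-Gaussian mixtures this lands within ~1 intensity unit on samples of
  the size a pooled ROI set provides.

Repetition semantics: the analysis is repeated three times, re-jittering
every ROI disk center by up to ±2 px (seeded) before recomputation, and the
three thresholds are averaged.  The jitter emulates repeated manual ROI
placement; what varies between repetitions is not specified by the
procedure the pipeline mirrors, so this choice is documented rather than
assumed known.

Tie rule: intensity exactly equal to the threshold counts as muscle.  The
classification contract assigns "lower" to muscle and "higher" to IntraMAT
and leaves equality open; ties are measure-zero for continuous data but
must be deterministic for integer-valued images.

Within-fascia sub-threshold pixels outside every muscle outline are counted
and reported as **unassigned**, not folded into InterMAT (which is defined
as *above*-threshold) nor into any muscle.  Consequently the SAT
subtraction identity (total − muscle − IntraMAT − InterMAT − femur) equals
directly-labelled SAT exactly whenever no pixel is unassigned, and
otherwise exceeds it by the unassigned count, which is reported.

Containment convention everywhere: 0-based pixel indices, polygon vertices
in pixel units, even-odd rule evaluated at pixel centers with half-open
edge handling — bit-stable across runs and platforms.

## Volumetry

CSA = pixel count × (FOV/matrix)²; volume = Σ eᵢ × CSAᵢ (rectangle rule);
IntraMAT content = IntraMAT/(muscle+IntraMAT) × 100.  All ratio quantities
(content, percentage change) are computed per subject and then averaged,
never as ratios of group means — the two differ by ~0.3 percentage points
on realistic tables.  Muscle groups are exact sums of their members;
aggregation refuses to produce a group when a member is missing (explicit
request) or silently skips it (automatic mode on partial-thigh tables).

## Statistics

The mixed ANOVA is computed from an explicit sums-of-squares decomposition
(weighted cell means; with one between-subject factor and two sessions the
decomposition is unambiguous) and agrees with pingouin's `mixed_anova` to
machine precision on balanced and unbalanced designs.  Partial η² =
SS_effect/(SS_effect + SS_error) with the within-subject error for time and
interaction and the between-subject error for group.  Fully constant data
are reported as degenerate (F = 0) rather than NaN.

Correlation power uses the Fisher z approximation in the form standard
power calculators use: the critical r comes from the exact t-based null
(df = n − 2) and the alternative distribution of atanh(r) is normal with
mean atanh(ρ) + ρ/(2(n−1)) and sd 1/√(n−3).  For |r| = 0.626, n = 13,
α = .05 this yields 0.669.  The plain approximation without the bias term
yields 0.642; the bias-corrected form was chosen as the more accurate and
more widely implemented variant, with a documented tolerance of ±0.03 when
comparing against published values whose approximation family is unstated.

Cohen's d (both for post-hoc paired contrasts and for the Aspin–Welch
comparison of percentage changes) uses the pooled standard deviation of the
two samples.  ICC(2,1) comes from the two-way mean squares; SEM =
sd × √(1 − ICC) with sd taken over all measurements.

## Synthetic data

The phantom emulates: the default acquisition geometry (450 × 270 mm FOV on
a 320 × 192 matrix, 12 mm slices, 12 mm gaps, up to 35 slices), a bimodal
intensity model (muscle mean 100, fat mean 200, femur 60, arbitrary units;
default noise sd 5 = SNR 20 at the muscle mode), a clamped second-order
polynomial bias field (range [0.8, 1.25], default ±15 % swing), wedge-
shaped muscle compartments arranged around a femur disk inside a fascia
ellipse with a SAT ring outside it, uniform-random IntraMAT speckle at a
prescribed per-muscle fraction (rounded to a whole pixel count), and
InterMAT speckle at a prescribed fraction of the inter-compartment space.
Noise is additive Gaussian by default with a Rician option; Gaussian keeps
the oracle arithmetic exact while Rician adds the magnitude-image floor for
realism checks.

It does **not** emulate: realistic muscle shapes or their slice-to-slice
variation (compartments are prismatic), partial-volume mixing at tissue
borders, spatially correlated noise, motion or chemical-shift artefacts, or
anatomically structured IntraMAT (fat infiltration along fascicles).
Passing recovery tests therefore demonstrates correctness of the
measurement chain under the stated intensity model, not robustness to
anatomy- or artefact-driven segmentation failure modes.

Cohorts: subjects receive a baseline size factor (CV 5 %) and per-structure
volume changes drawn from the effect model (mean, between-subject sd, in
cm³).  Drawn volumes are recorded analytically and exactly in the cohort
table — this is the ground truth used by statistical tests.  Rendering,
when requested, rescales compartment polygons radially about the fascia
center in normalised elliptic coordinates (preserving their angular
disjointness, clamped away from femur and fascia), so rendered volumes
track the drawn ones only up to pixelation (≈1–3 %).

## Problem sizes

Tests and examples run phantoms of 1–8 slices with 2–4 compartments and
cohorts of 2–8 subjects per group; the design-power property uses 200
simulated cohorts at n = 7–8 per group on the analytic volume path.  These
sizes were chosen so the full suite exercises every stage end to end in
well under a minute per test while leaving the estimators' error margins
(3 % volume, ±0.03 IntraMAT fraction, 2-unit threshold accuracy) clearly
resolvable.

## Known limitations

* The bias-field loop is a faithful re-implementation of the N3 scheme,
  not a numerical twin of any particular historical binary; convergence
  trajectories differ even where the corrected images agree.
* At low SNR the estimated field absorbs noise structure (see above);
  interpret the field itself only on high-SNR or noiseless data.
* Unequal-group mixed ANOVA uses the weighted (Type I/II-equivalent)
  decomposition natural to a single between-subject factor; with more
  complex designs the decomposition would need revisiting.
* The automatic ROI placement is a stand-in for expert placement; it
  requires each sampled muscle compartment to admit an interior disk and
  the SAT ring to be at least as wide as the disk diameter.
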