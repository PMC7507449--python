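# thighcomp

Quantification of thigh composition — skeletal muscle tissue, intramuscular
(IntraMAT), intermuscular (InterMAT) and subcutaneous (SAT) adipose tissue —
from axial T1-weighted MR image stacks, together with the statistical
battery used in longitudinal disuse/training studies of the thigh.  It is
aimed at muscle-physiology and body-composition researchers who segment
serially acquired thigh slices with traced muscle outlines and need
reproducible volumes, IntraMAT content, and before/after statistics.

## Method

On T1-weighted images muscle is hypointense and adipose tissue
hyperintense, so tissue composition can be read off per pixel once two
problems are solved:

1. **Intensity nonuniformity.** Radiofrequency-coil imperfections impose a
   smooth multiplicative bias field b(x) on the true signal.  Each slice is
   corrected with an N3-style algorithm: iteratively sharpen the
   log-intensity histogram of signal pixels by Wiener deconvolution of a
   Gaussian kernel, map each pixel to E[u | v] under the sharpened
   distribution, smooth the residual v − E[u | v] with a tensor-product
   cubic B-spline (control-point spacing 25 mm), and accumulate, until the
   coefficient of variation of the between-iteration field ratio falls
   below 10⁻⁴ (at most 100 iterations; signal threshold 1; subsampling
   factor 4; kernel FWHM 0.15; Wiener noise 0.01).

2. **Muscle/fat threshold.** Disk ROIs are sampled in muscle tissue and in
   SAT; the pooled intensity histogram is bimodal, and the threshold is
   isolated at the base of the first (muscle) peak — the minimum of the
   smoothed valley between the two modes.  The determination is repeated
   three times with re-jittered ROI placement and averaged.

Pixels inside each traced muscle outline are then counted as muscle tissue
(intensity ≤ threshold) or IntraMAT (> threshold), and converted by

    CSA [cm²]    = pixel count × (FOV / matrix)²
    volume [cm³] = Σᵢ eᵢ × CSAᵢ          (eᵢ = inter-slice spacing)
    IntraMAT content [%] = IntraMAT / (muscle + IntraMAT) × 100

with InterMAT (above-threshold pixels deep to the fascia, outside every
muscle), SAT (between fascia and skin) and the femur completing an exact
partition of the slice.  Muscles aggregate into quadriceps femoris
(QF = RF+VL+VI+VM), hamstrings (HM = BFs+BFl+ST+SM), hip adductors
(AD = AL+AM+AB+Sar+Gr) and the whole thigh.

The statistics module provides two-factor repeated-measures (mixed) ANOVA
with partial η², Bonferroni post-hoc tests with Cohen's d, within-group
changes with t-based 95 % CIs, the Aspin–Welch unequal-variance t test,
Pearson correlation with post-hoc power (Fisher z approximation), and
ICC(2,1) with SEM for reproducibility analysis.

Because no imaging data are distributed, a synthetic phantom generator
renders thigh cross-sections with known ground truth (polygonal muscle
compartments, adipose speckle at prescribed fractions, a polynomial bias
field, Gaussian or Rician noise) and longitudinal two-group cohorts with
prescribed volume effects, so every stage is testable end to end.

## Worked example

```python
import thighcomp as tc
from thighcomp.bias import correct_stack
from thighcomp.segmentation import (place_rois, compute_threshold,
                                    classify_slice, outlines_from_spec)
from thighcomp.volumetrics import csa_from_pixels, integrate_volume, intramat_content

spec = tc.default_phantom_spec(muscles=["RF", "VL", "VI", "VM"], n_slices=8,
                               intramat_fraction=0.15, noise_sd=5.0, seed=42)
stack, truth = tc.generate_phantom(spec)
corrected, fields = correct_stack(stack.data,
                                  pixel_spacing_mm=spec.geometry.pixel_spacing_mm)
outlines = outlines_from_spec(spec)
csas = {"muscle": [], "intramat": []}
for s in range(stack.n_slices):
    rois = place_rois(corrected[s], outlines)
    thr = compute_threshold(corrected[s], rois, seed=s)
    labels = classify_slice(corrected[s], outlines, thr.threshold)
    total, n_mus, n_fat = labels.muscle_counts("VL")
    csas["muscle"].append(csa_from_pixels(n_mus, spec.geometry))
    csas["intramat"].append(csa_from_pixels(n_fat, spec.geometry))
v_mus = integrate_volume(csas["muscle"], spec.geometry)
v_fat = integrate_volume(csas["intramat"], spec.geometry)
print(f"VL muscle-tissue volume: {v_mus:.1f} cm^3")
print(f"VL IntraMAT volume:      {v_fat:.1f} cm^3")
print(f"VL IntraMAT content:     {intramat_content(v_mus, v_fat):.2f} %")
```

prints

```
VL muscle-tissue volume: 665.6 cm^3
VL IntraMAT volume:      117.3 cm^3
VL IntraMAT content:     14.99 %
```

— the vastus lateralis compartment was simulated with a 15 % IntraMAT
fraction under a ±15 % bias field at SNR 20, and the pipeline recovers its
muscle-tissue and IntraMAT volumes exactly (ground truth 665.6 / 117.3 cm³)
after bias correction and automatic thresholding.

A full simulate→correct→segment→volumes→stats run is driven by one config:

```
thighcomp run --config run.yaml --seed 1
```

and writes per-slice CSA tables, per-subject volume tables (with units
rows), the statistical report, and a manifest with config hash and output
checksums.

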