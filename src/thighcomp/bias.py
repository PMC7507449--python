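"""N3-style multiplicative bias-field estimation and correction.

T1-weighted images carry a smooth multiplicative intensity nonuniformity
("bias field") from radiofrequency coil imperfections; it must be divided
out before any intensity-threshold segmentation.  The estimator here is the
classic nonparametric nonuniformity normalisation scheme: model the observed
log-intensity v as the true log-signal u plus a smooth log-bias b, assume b
blurs the intensity distribution with an approximately Gaussian kernel, and
iterate

1. histogram the (corrected) log intensities of signal pixels;
2. sharpen the histogram by Wiener deconvolution of a Gaussian of the given
   full width at half maximum;
3. map each pixel to its conditional expectation E[u | v] under the
   sharpened distribution; the residual v - E[u | v] is the pointwise
   log-bias estimate;
4. smooth the residual with a tensor-product cubic spline whose
   control-point spacing is the field distance, and accumulate it;

until the coefficient of variation of the between-iteration field ratio
falls below the end tolerance or the iteration cap is reached.  Correction
is performed per slice (slices are analysed independently and the slice gap
is large), and the corrected slice is rescaled so the mean intensity over
signal pixels is preserved.

Defaults: end tolerance 0.0001, at most 100 iterations, signal threshold 1,
field distance 25 mm, subsampling factor 4, kernel FWHM 0.15 (log-intensity
units), Wiener noise 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LSQBivariateSpline

from .errors import InputError, NoSignalError

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class N3Params:
    end_tolerance: float = 0.0001
    max_iterations: int = 100
    signal_threshold: float = 1.0
    field_distance_mm: float = 25.0
    subsampling_factor: int = 4
    kernel_fwhm: float = 0.15
    wiener_noise: float = 0.01
    n_bins: int = 200

    def validate(self) -> None:
        numeric = dict(end_tolerance=self.end_tolerance,
                       signal_threshold=self.signal_threshold,
                       field_distance_mm=self.field_distance_mm,
                       kernel_fwhm=self.kernel_fwhm,
                       wiener_noise=self.wiener_noise)
        for name, value in numeric.items():
            if not value > 0:
                raise InputError(f"{name} must be strictly positive")
        if self.max_iterations < 1:
            raise InputError("max_iterations must be at least 1")
        if self.subsampling_factor < 1:
            raise InputError("subsampling_factor must be at least 1")
        if self.n_bins < 8:
            raise InputError("histogram needs at least 8 bins")


@dataclass
class BiasField:
    """Estimated multiplicative field on the slice grid (mean 1 over signal)."""

    field: np.ndarray
    iterations_used: int
    converged: bool
    mask: np.ndarray  # signal pixels the field was fitted on
    cv_history: list


def _sharpen(counts: np.ndarray, bin_width: float, params: N3Params) -> np.ndarray:
    """Wiener-deconvolve a Gaussian blur from the histogram; clip to >= 0."""
    sigma_bins = params.kernel_fwhm * _FWHM_TO_SIGMA / bin_width
    n = counts.size
    m = 1 << int(np.ceil(np.log2(2 * n)))  # zero-pad to avoid wrap-around
    freq = np.fft.rfftfreq(m)
    # unit-area Gaussian kernel, frequency domain (real, even kernel)
    g_hat = np.exp(-2.0 * (np.pi * freq * sigma_bins) ** 2)
    f_hat = np.fft.rfft(counts, m)
    u_hat = f_hat * g_hat / (g_hat ** 2 + params.wiener_noise)
    u = np.fft.irfft(u_hat, m)[:n]
    return np.clip(u, 0.0, None)


def _expected_log_signal(v, centers, sharpened, bin_width, params):
    """E[u | v] under the sharpened distribution blurred by the kernel."""
    sigma = params.kernel_fwhm * _FWHM_TO_SIGMA
    half = int(np.ceil(4.0 * sigma / bin_width)) + 1
    t = np.arange(-half, half + 1) * bin_width
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    den = np.convolve(sharpened, kernel, mode="same")
    num = np.convolve(sharpened * centers, kernel, mode="same")
    mapping = num / np.maximum(den, 1e-30)
    # outside the populated range the ratio is meaningless; pin to identity
    bad = den < 1e-12 * den.max()
    mapping[bad] = centers[bad]
    return np.interp(v, centers, mapping)


def _smooth_residual(rows, cols, r, shape, spacing_px):
    """Least-squares tensor cubic spline with knots every ``spacing_px``."""
    h, w = shape
    tx = np.arange(spacing_px, h - 1, spacing_px, dtype=float)
    ty = np.arange(spacing_px, w - 1, spacing_px, dtype=float)
    try:
        with warnings.catch_warnings():
            # knot cells outside the signal support are rank deficient by
            # construction; the minimal-norm solution is what we want there
            warnings.simplefilter("ignore")
            spl = LSQBivariateSpline(rows, cols, r, tx, ty, kx=3, ky=3)
        gr, gc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                             indexing="ij")
        return spl.ev(gr.ravel(), gc.ravel()).reshape(shape)
    except Exception:
        # degenerate geometry (tiny slices, too few points per knot cell):
        # fall back to a global cubic polynomial surface
        x = (cols - w / 2.0) / max(w, 1)
        y = (rows - h / 2.0) / max(h, 1)
        terms = [np.ones_like(x), x, y, x * y, x ** 2, y ** 2,
                 x ** 3, y ** 3, x ** 2 * y, x * y ** 2]
        a = np.column_stack(terms)
        coef, *_ = np.linalg.lstsq(a, r, rcond=None)
        gr, gc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                             indexing="ij")
        gx = (gc.ravel() - w / 2.0) / max(w, 1)
        gy = (gr.ravel() - h / 2.0) / max(h, 1)
        gterms = np.column_stack([np.ones_like(gx), gx, gy, gx * gy, gx ** 2, gy ** 2,
                                  gx ** 3, gy ** 3, gx ** 2 * gy, gx * gy ** 2])
        return (gterms @ coef).reshape(shape)


def estimate_bias_field(
    slice_: np.ndarray,
    params: N3Params | None = None,
    pixel_spacing_mm: tuple[float, float] = (1.40625, 1.40625),
    mask: np.ndarray | None = None,
) -> BiasField:
    """Estimate the multiplicative bias field of one axial slice.

    Pixels below the signal threshold are excluded from fitting (the
    returned field is still defined everywhere via the spline); an
    explicit ``mask`` restricts fitting further, e.g. to the imaged limb
    so that air pixels whose noise tops the threshold cannot distort the
    intensity modes.  Raises :class:`NoSignalError` if no pixel reaches
    the signal threshold and :class:`InputError` for non-finite input.
    """
    params = params or N3Params()
    params.validate()
    img = np.asarray(slice_, dtype=float)
    if img.ndim != 2:
        raise InputError(f"expected a 2-D slice; got shape {img.shape}")
    if not np.isfinite(img).all():
        raise InputError("slice contains non-finite values")
    if (img < 0).any():
        raise InputError("slice intensities must be non-negative")
    mask = (img >= params.signal_threshold) if mask is None \
        else (np.asarray(mask, dtype=bool) & (img >= params.signal_threshold))
    if not mask.any():
        raise NoSignalError("no pixel reaches the signal threshold")

    h, w = img.shape
    f = params.subsampling_factor
    sub = np.zeros_like(mask)
    sub[::f, ::f] = True
    sub &= mask
    if sub.sum() < 16:  # tiny slice: use every signal pixel
        sub = mask
    rows, cols = np.nonzero(sub)
    v0 = np.log(img[rows, cols])

    spacing = float(np.mean(pixel_spacing_mm))
    knot_px = max(params.field_distance_mm / spacing, 2.0)

    log_field = np.zeros(img.shape)
    converged = False
    cv_history: list[float] = []
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        v = v0 - log_field[rows, cols]
        if v.max() - v.min() < 1e-9:  # already uniform: nothing to correct
            cv_history.append(0.0)
            converged = True
            break
        # pad the range so no intensity mode is truncated at a histogram
        # boundary, which would bias E[u | v] near the edges
        pad = 4.0 * params.kernel_fwhm * _FWHM_TO_SIGMA
        lo, hi = v.min() - pad, v.max() + pad
        counts, edges = np.histogram(v, bins=params.n_bins, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        bin_width = edges[1] - edges[0]
        sharpened = _sharpen(counts.astype(float), bin_width, params)
        if sharpened.sum() <= 0:
            sharpened = counts.astype(float)
        expected = _expected_log_signal(v, centers, sharpened, bin_width, params)
        residual = v - expected
        smooth = _smooth_residual(rows.astype(float), cols.astype(float),
                                  residual, img.shape, knot_px)
        smooth -= smooth[mask].mean()  # keep the field mean-one over signal
        log_field += smooth
        ratio = np.exp(smooth[mask])
        cv = float(ratio.std() / ratio.mean())
        cv_history.append(cv)
        if cv < params.end_tolerance:
            converged = True
            break

    # the spline extrapolates freely outside the fitted mask; clamp so the
    # field stays positive and bounded everywhere on the grid
    field = np.exp(np.clip(log_field, -3.0, 3.0))
    field /= field[mask].mean()
    return BiasField(field=field, iterations_used=iterations,
                     converged=converged, mask=mask, cv_history=cv_history)


def apply_correction(
    slice_: np.ndarray,
    field: BiasField | np.ndarray,
    signal_threshold: float = 1.0,
) -> np.ndarray:
    """Divide the slice by the field, preserving mean signal intensity.

    The output mean over signal pixels (intensity >= ``signal_threshold``
    in the input) equals the input mean over the same pixels.
    """
    img = np.asarray(slice_, dtype=float)
    arr = field.field if isinstance(field, BiasField) else np.asarray(field, dtype=float)
    if arr.shape != img.shape:
        raise InputError(f"field shape {arr.shape} does not match slice {img.shape}")
    if (arr <= 0).any():
        raise InputError("bias field must be strictly positive")
    corrected = img / arr
    mask = img >= signal_threshold
    if mask.any() and corrected[mask].mean() > 0:
        corrected *= img[mask].mean() / corrected[mask].mean()
    return corrected


def correct_stack(
    stack_data: np.ndarray,
    params: N3Params | None = None,
    pixel_spacing_mm: tuple[float, float] = (1.40625, 1.40625),
) -> tuple[np.ndarray, list[BiasField]]:
    """Per-slice bias correction of a (slices, rows, cols) array.

    Fitting is restricted to the imaged limb (largest connected
    supra-threshold component) on each slice.
    """
    from ._image import body_mask

    params = params or N3Params()
    corrected = np.empty_like(stack_data, dtype=float)
    fields = []
    for s in range(stack_data.shape[0]):
        limb = body_mask(stack_data[s], params.signal_threshold)
        bf = estimate_bias_field(stack_data[s], params, pixel_spacing_mm, mask=limb)
        corrected[s] = apply_correction(stack_data[s], bf, params.signal_threshold)
        fields.append(bf)
    return corrected, fields
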