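"""Bimodal-histogram thresholding and tissue classification.

On a bias-corrected T1-weighted slice, muscle is hypointense and adipose
tissue hyperintense, so the intensity histogram of a sample drawn from
muscle and subcutaneous fat regions is bimodal.  The muscle/fat threshold is
isolated at the base of the first (muscle) peak: the first local minimum of
the smoothed histogram above the first mode.  The determination is repeated
(three times by default) with re-jittered region-of-interest placements and
the repetition thresholds are averaged.

Pixels inside each traced muscle boundary are then counted as muscle tissue
(intensity at or below the threshold) or IntraMAT (above it); within-fascia
pixels outside every muscle are InterMAT when above the threshold and
reported as "unassigned" otherwise; pixels between the fascia and the outer
skin boundary are SAT; the femur interior is its own class.  The classes
partition the image, so SAT obtained by direct labelling coincides with the
total-minus-parts subtraction whenever no pixel is unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from . import anatomy
from ._image import body_mask
from ._raster import disk_mask, polygon_mask
from .errors import BimodalityError, GeometryError, InputError, NamingError

DEFAULT_BINS = 256
DEFAULT_SMOOTH_SIGMA = 2.0  # bins
DEFAULT_REPETITIONS = 3
JITTER_PX = 2


@dataclass(frozen=True)
class SliceOutlineSet:
    """Named closed polygons for one slice: muscles, fascia, femur.

    Vertices are (x, y) pixel coordinates (0-based, vertex at pixel center);
    polygons are implicitly closed; containment is by the even-odd rule on
    pixel centers.
    """

    slice_index: int
    polygons: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name, verts in self.polygons.items():
            if name not in anatomy.OUTLINE_NAMES:
                raise NamingError(name, anatomy.OUTLINE_NAMES)
            v = np.asarray(verts, dtype=float)
            n = len(v) - (1 if len(v) > 1 and np.allclose(v[0], v[-1]) else 0)
            if v.ndim != 2 or v.shape[1] != 2 or n < 3:
                raise GeometryError(
                    f"polygon {name!r} on slice {self.slice_index} is malformed "
                    f"(needs >= 3 distinct (x, y) vertices)"
                )

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(n for n in self.polygons if n in anatomy.MUSCLES)

    def require(self, *names: str) -> None:
        for n in names:
            if n not in self.polygons:
                raise InputError(f"slice {self.slice_index}: missing outline {n!r}")


@dataclass(frozen=True)
class RoiSample:
    """Disk ROIs sampling muscle tissue and SAT intensities on one slice."""

    muscle_disks: tuple[tuple[tuple[float, float], float], ...]
    sat_disks: tuple[tuple[tuple[float, float], float], ...]

    def pooled(self, slice_: np.ndarray, jitter=None) -> np.ndarray:
        """Pooled intensity sample over all disks (optionally jittered).

        ``jitter`` maps disk index (0..5) to an (dx, dy) integer offset.
        """
        shape = slice_.shape
        values = []
        for i, (center, radius) in enumerate(self.muscle_disks + self.sat_disks):
            cx, cy = center
            if jitter is not None and i in jitter:
                dx, dy = jitter[i]
                cx, cy = cx + dx, cy + dy
            if not (0 <= cx < shape[1] and 0 <= cy < shape[0]):
                raise GeometryError(f"ROI center ({cx}, {cy}) outside image {shape}")
            values.append(slice_[disk_mask((cx, cy), radius, shape)])
        return np.concatenate(values)


@dataclass
class ThresholdResult:
    repetition_thresholds: list
    threshold: float
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class TissueLabelMap:
    """Per-pixel tissue classes for one slice (codes in :mod:`anatomy`)."""

    class_map: np.ndarray  # (H, W) uint8
    muscle_id: np.ndarray  # (H, W) uint8, 1-based index into ``muscles``
    muscles: tuple[str, ...]
    threshold: float

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.class_map == code).sum())
                for code, name in anatomy.CLASS_NAMES.items()}

    def muscle_counts(self, muscle: str) -> tuple[int, int, int]:
        mid = self.muscles.index(muscle) + 1
        sel = self.muscle_id == mid
        n_mus = int((sel & (self.class_map == anatomy.MUSCLE)).sum())
        n_fat = int((sel & (self.class_map == anatomy.INTRAMAT)).sum())
        return n_mus + n_fat, n_mus, n_fat


def sat_csa_by_subtraction(total_thigh, muscle, intramat, intermat, femur):
    """SAT CSA as total thigh minus (muscle + IntraMAT + InterMAT + femur)."""
    return total_thigh - (muscle + intramat + intermat + femur)


# ---------------------------------------------------------------------------
# threshold determination

def _first_valley(sample: np.ndarray, bins: int, sigma: float):
    """Threshold at the base of the first peak of the smoothed histogram."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 60:
        raise InputError("pooled ROI sample too small (need >= 60 pixels)")
    lo, hi = sample.min(), sample.max()
    if hi - lo <= 0:
        raise BimodalityError("constant intensity sample has no modes")
    # pad the range so a mode sitting at an extreme of the sample still
    # appears as an interior peak of the smoothed histogram
    pad = 0.02 * (hi - lo)
    counts, edges = np.histogram(sample, bins=bins, range=(lo - pad, hi + pad))
    smoothed = gaussian_filter1d(counts.astype(float), sigma, mode="nearest")
    # a mode must rise well clear of the valley floor; with balanced
    # muscle/SAT ROI pooling both genuine modes easily do, while sampling
    # wiggle on a sparse histogram does not
    prominence = 0.2 * smoothed.max()
    peaks, _ = find_peaks(smoothed, prominence=prominence)
    if peaks.size < 2:
        raise BimodalityError(
            f"histogram has {peaks.size} mode(s) after smoothing; "
            "expected a bimodal muscle/fat sample"
        )
    p1, p2 = peaks[0], peaks[1]
    between = smoothed[p1:p2 + 1]
    # base of the first peak: the minimum of the smoothed valley between
    # the two modes.  When the valley floor is a flat (often zero-count)
    # plateau, its midpoint is taken, which for well-separated modes
    # coincides with the mixture-density minimum.
    floor = between.min()
    at_floor = np.flatnonzero(between <= floor + 1e-12 * max(floor, 1.0))
    valley = p1 + int(round(at_floor.mean()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    threshold = float(centers[valley])
    # sub-bin refinement: vertex of a quadratic fitted around the argmin
    # (populated valleys only; a zero-count plateau keeps its midpoint)
    half = 8
    w_lo, w_hi = max(p1 + 1, valley - half), min(p2 - 1, valley + half)
    if w_hi - w_lo >= 4 and smoothed[valley] > 0:
        coef = np.polyfit(centers[w_lo:w_hi + 1], smoothed[w_lo:w_hi + 1], 2)
        if coef[0] > 0:
            vx = -coef[1] / (2.0 * coef[0])
            if centers[w_lo] <= vx <= centers[w_hi]:
                threshold = float(vx)
    return threshold, edges, counts


def compute_threshold(
    slice_: np.ndarray,
    rois: RoiSample,
    n_repetitions: int = DEFAULT_REPETITIONS,
    seed: int | None = 0,
    bins: int = DEFAULT_BINS,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
) -> ThresholdResult:
    """Average of repeated bimodal-histogram threshold determinations.

    The first repetition uses the ROI disks as given; subsequent repetitions
    re-jitter each disk center by up to +/-2 px (seeded), mimicking repeated
    manual placement.  Raises :class:`BimodalityError` when the pooled
    sample does not show two modes.
    """
    if n_repetitions < 1:
        raise InputError("need at least one repetition")
    rng = np.random.default_rng(seed)
    n_disks = len(rois.muscle_disks) + len(rois.sat_disks)
    thresholds = []
    edges = counts = None
    for rep in range(n_repetitions):
        jitter = None
        if rep > 0:
            jitter = {i: tuple(rng.integers(-JITTER_PX, JITTER_PX + 1, size=2))
                      for i in range(n_disks)}
        sample = rois.pooled(slice_, jitter)
        thr, e, c = _first_valley(sample, bins, smooth_sigma)
        thresholds.append(thr)
        if rep == 0:
            edges, counts = e, c
    return ThresholdResult(
        repetition_thresholds=thresholds,
        threshold=float(np.mean(thresholds)),
        bin_edges=edges,
        counts=counts,
    )


def place_rois(
    slice_: np.ndarray,
    outlines: SliceOutlineSet,
    radius: float = 6.0,
    background_threshold: float = 1.0,
    n_each: int = 3,
) -> RoiSample:
    """Automatic stand-in for manual ROI placement.

    Muscle disks go at the interior of the ``n_each`` largest muscle
    polygons; SAT disks at three angles in the ring between the fascia
    outline and the outer skin boundary (the connected supra-background
    component).
    """
    outlines.require(anatomy.FASCIA)
    shape = slice_.shape
    areas = []
    for name in outlines.muscles:
        mask = polygon_mask(outlines.polygons[name], shape)
        areas.append((mask.sum(), name, mask))
    areas.sort(reverse=True, key=lambda t: t[0])
    if len(areas) < 1:
        raise InputError("no muscle outline available for ROI placement")
    muscle_disks = []
    for _, name, mask in areas[:n_each]:
        eroded = ndimage.binary_erosion(mask, iterations=int(radius) + JITTER_PX + 1)
        target = eroded if eroded.any() else mask
        dist = ndimage.distance_transform_edt(target)
        r, c = np.unravel_index(np.argmax(dist), shape)
        muscle_disks.append(((float(c), float(r)), radius))
    while len(muscle_disks) < n_each:  # fewer muscles than disks: reuse
        muscle_disks.append(muscle_disks[len(muscle_disks) % len(areas)])

    body = _body_mask(slice_, background_threshold)
    fascia = polygon_mask(outlines.polygons[anatomy.FASCIA], shape)
    ring = body & ~fascia
    ring_eroded = ndimage.binary_erosion(ring, iterations=int(radius) + JITTER_PX + 1)
    target = ring_eroded if ring_eroded.any() else ring
    if not target.any():
        raise GeometryError("no SAT ring found outside the fascia outline")
    rr, cc = np.nonzero(target)
    cy, cx = rr.mean(), cc.mean()
    ang = np.arctan2(rr - cy, cc - cx)
    sat_disks = []
    for theta in np.deg2rad([90.0, 210.0, 330.0])[:n_each]:
        diff = np.abs(np.angle(np.exp(1j * (ang - theta))))
        k = int(np.argmin(diff))
        sat_disks.append(((float(cc[k]), float(rr[k])), radius))
    return RoiSample(muscle_disks=tuple(muscle_disks), sat_disks=tuple(sat_disks))


# ---------------------------------------------------------------------------
# pixel classification

def classify_muscle_pixels(slice_, outline, threshold: float):
    """(total, muscle, IntraMAT) pixel counts within one muscle polygon.

    Intensity at or below the threshold counts as muscle tissue, above it
    as IntraMAT (ties go to muscle).
    """
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    mask = polygon_mask(outline, slice_.shape)
    total = int(mask.sum())
    if total == 0:
        raise GeometryError("muscle polygon contains no pixel centers")
    vals = np.asarray(slice_)[mask]
    n_muscle = int((vals <= threshold).sum())
    return total, n_muscle, total - n_muscle


def _body_mask(slice_, background_threshold: float) -> np.ndarray:
    return body_mask(slice_, background_threshold)


def classify_slice(
    slice_: np.ndarray,
    outlines: SliceOutlineSet,
    threshold: float,
    background_threshold: float = 1.0,
) -> TissueLabelMap:
    """Full tissue label map for one slice.

    Requires fascia and femur outlines.  The outer skin boundary is the
    largest connected supra-background component; SAT is that body mask
    outside the fascia.  The classes partition the image.
    """
    outlines.require(anatomy.FASCIA, anatomy.FEMUR)
    img = np.asarray(slice_, dtype=float)
    shape = img.shape
    body = _body_mask(img, background_threshold)
    fascia = polygon_mask(outlines.polygons[anatomy.FASCIA], shape)
    femur = polygon_mask(outlines.polygons[anatomy.FEMUR], shape)

    class_map = np.zeros(shape, dtype=np.uint8)
    muscle_id = np.zeros(shape, dtype=np.uint8)
    class_map[body] = anatomy.SAT
    inside = fascia.copy()
    muscles = outlines.muscles
    claimed = np.zeros(shape, dtype=bool)
    for i, name in enumerate(muscles, start=1):
        mask = polygon_mask(outlines.polygons[name], shape)
        if (mask & claimed).any():
            raise GeometryError(f"muscle {name} overlaps a previously traced muscle")
        claimed |= mask
        vals = img[mask]
        sub = np.zeros(shape, dtype=bool)
        sub[mask] = vals <= threshold
        class_map[mask] = anatomy.INTRAMAT
        class_map[sub] = anatomy.MUSCLE
        muscle_id[mask] = i
    gap = inside & ~claimed & ~femur
    above = gap & (img > threshold)
    class_map[gap] = anatomy.UNASSIGNED
    class_map[above] = anatomy.INTERMAT
    class_map[femur] = anatomy.FEMUR_CLASS
    muscle_id[femur] = 0
    return TissueLabelMap(class_map=class_map, muscle_id=muscle_id,
                          muscles=muscles, threshold=float(threshold))


def label_map_to_csa_rows(label_map: TissueLabelMap, slice_index: int, geom,
                          subject: str = "-", session: str = "-") -> list[dict]:
    """Rows for the per-slice CSA table (see :mod:`thighcomp.volumetrics`)."""
    px = geom.pixel_area_cm2
    rows = []
    for m in label_map.muscles:
        _, n_mus, n_fat = label_map.muscle_counts(m)
        rows.append(dict(subject=subject, session=session, slice_index=slice_index,
                         structure=m, muscle_csa_cm2=n_mus * px,
                         intramat_csa_cm2=n_fat * px))
    counts = label_map.class_counts()
    for structure in ("InterMAT", "SAT", "femur", "unassigned"):
        rows.append(dict(subject=subject, session=session, slice_index=slice_index,
                         structure=structure, muscle_csa_cm2=0.0,
                         intramat_csa_cm2=0.0,
                         class_csa_cm2=counts[structure] * px))
    return rows


def outlines_from_spec(spec, slice_index: int = 0) -> SliceOutlineSet:
    """Traced-outline stand-in derived from a phantom specification."""
    from ._raster import ellipse_polygon

    polygons: dict[str, np.ndarray] = {
        name: np.asarray(poly, dtype=float)
        for name, poly in spec.muscle_compartments.items()
    }
    polygons[anatomy.FASCIA] = ellipse_polygon(*spec.fascia_ellipse)
    center, radius = spec.femur_disk
    polygons[anatomy.FEMUR] = ellipse_polygon(center, (radius, radius))
    return SliceOutlineSet(slice_index=slice_index, polygons=polygons)
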