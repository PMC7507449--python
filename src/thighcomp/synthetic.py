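"""Synthetic thigh phantoms and longitudinal cohorts with known ground truth.

No imaging data accompany the study design this package implements, so every
pipeline stage is exercised against simulated axial T1-weighted slices whose
tissue composition is known exactly.  A phantom is a prismatic thigh
cross-section: an outer skin ellipse, a subcutaneous adipose (SAT) ring, a
deep-fascia ellipse, wedge-shaped muscle compartments arranged around a
femur disk, adipose speckle inside each muscle (IntraMAT) and in the
inter-compartment space (InterMAT).  The rendered image is

    image = tissue_template * bias_field + noise

where the bias field is a smooth multiplicative second-order polynomial
(range-clamped), emulating radiofrequency coil nonuniformity, and noise is
additive Gaussian by default (Rician optionally, for realism checks).

Intensities are bimodal by construction — a low muscle mode and a high fat
mode — which is the premise of the histogram-threshold segmentation.

The longitudinal cohort generator assigns subjects to a resistance-exercise
intervention (TR) or bed-rest control (CTR) group and draws per-subject
before/after volume changes from a per-structure effect model.  Drawn
volumes are recorded analytically (exact), and images approximating them can
optionally be rendered by rescaling the template geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anatomy
from ._raster import ellipse_polygon, polygon_mask
from .errors import DesignError, GeometryError, ModelError
from .volumetrics import AcquisitionGeometry

# -- default acquisition geometry: 450 x 270 mm field of view on a
#    320 x 192 matrix (1.40625 mm isotropic pixels), 12 mm slices with a
#    12 mm gap, i.e. 24 mm center-to-center spacing
DEFAULT_MATRIX = (320, 192)          # rows, cols
DEFAULT_FOV_MM = (450.0, 270.0)      # height, width
DEFAULT_SLICE_THICKNESS_MM = 12.0
DEFAULT_INTERSLICE_GAP_MM = 12.0

# default intensity model (arbitrary units); SNR 20 at the muscle mode
DEFAULT_MUSCLE_MEAN = 100.0
DEFAULT_FAT_MEAN = 200.0
DEFAULT_FEMUR_MEAN = 60.0
DEFAULT_NOISE_SD = 5.0

# default bias polynomial over normalised coordinates u, v in [-1, 1]:
# b = c0 + c1 u + c2 v + c3 u^2 + c4 u v + c5 v^2, clamped to [0.8, 1.25].
# These coefficients give roughly a +/-15% swing across the matrix.
DEFAULT_BIAS_COEFFS = (1.02, 0.10, -0.08, -0.07, 0.04, 0.06)
UNIT_BIAS_COEFFS = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
BIAS_CLAMP = (0.8, 1.25)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic thigh phantom.

    ``muscle_compartments`` maps muscle name -> (n, 2) vertex array in
    (x, y) pixel coordinates; polygons must lie inside the fascia ellipse
    and be pairwise non-overlapping.  ``intramat_fractions`` gives, per
    muscle, the fraction of its pixels rendered as adipose speckle;
    ``intermat_fraction`` the fraction of within-fascia, extra-muscular,
    extra-femoral pixels rendered as adipose.
    """

    image_height_px: int = DEFAULT_MATRIX[0]
    image_width_px: int = DEFAULT_MATRIX[1]
    fov_mm: tuple[float, float] = DEFAULT_FOV_MM
    n_slices: int = 8
    slice_thickness_mm: float = DEFAULT_SLICE_THICKNESS_MM
    interslice_gap_mm: float = DEFAULT_INTERSLICE_GAP_MM
    outer_ellipse: tuple[tuple[float, float], tuple[float, float]] = ((96.0, 160.0), (86.0, 98.0))
    fascia_ellipse: tuple[tuple[float, float], tuple[float, float]] = ((96.0, 160.0), (62.0, 70.0))
    femur_disk: tuple[tuple[float, float], float] = ((96.0, 150.0), 12.0)
    muscle_compartments: dict[str, np.ndarray] = field(default_factory=dict)
    intramat_fractions: dict[str, float] = field(default_factory=dict)
    intermat_fraction: float = 0.15
    muscle_mean: float = DEFAULT_MUSCLE_MEAN
    fat_mean: float = DEFAULT_FAT_MEAN
    femur_mean: float = DEFAULT_FEMUR_MEAN
    noise_sd: float = DEFAULT_NOISE_SD
    noise_model: str = "gaussian"  # or "rician"
    bias_coeffs: tuple[float, ...] = DEFAULT_BIAS_COEFFS
    bias_clamp: tuple[float, float] = BIAS_CLAMP
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_height_px, self.image_width_px)

    @property
    def geometry(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            fov_mm=self.fov_mm,
            matrix_px=(self.image_height_px, self.image_width_px),
            slice_thickness_mm=self.slice_thickness_mm,
            interslice_gap_mm=self.interslice_gap_mm,
        )

    def validate(self) -> None:
        if self.fat_mean <= self.muscle_mean:
            raise ModelError(
                f"fat mean ({self.fat_mean}) must exceed muscle mean ({self.muscle_mean})"
            )
        if self.noise_sd < 0:
            raise ModelError("noise sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ModelError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.intermat_fraction < 1.0:
            raise ModelError("InterMAT fraction must lie in [0, 1)")
        for name, frac in self.intramat_fractions.items():
            if not 0.0 <= frac < 1.0:
                raise ModelError(f"IntraMAT fraction for {name} must lie in [0, 1)")
        for name in self.muscle_compartments:
            if name not in anatomy.MUSCLES:
                raise GeometryError(f"unknown muscle name {name!r}")
        if self.n_slices < 1:
            raise GeometryError("need at least one slice")


@dataclass(frozen=True)
class AxialImageStack:
    """Grayscale axial slices plus the spacing metadata needed downstream."""

    data: np.ndarray  # (n_slices, rows, cols) float32
    geometry: AcquisitionGeometry

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


class GroundTruth:
    """Per-pixel labels and exact tissue areas/volumes for one phantom.

    ``class_map`` holds the tissue class of every pixel (codes in
    :mod:`thighcomp.anatomy`); ``muscle_id`` holds 0 for no muscle or the
    1-based index into ``muscles`` for pixels inside a muscle compartment
    (including its IntraMAT speckle).  Class pixel counts times the pixel
    area reproduce every true CSA exactly.
    """

    def __init__(self, class_map, muscle_id, muscles, bias_field, geometry):
        self.class_map = class_map          # (S, H, W) uint8
        self.muscle_id = muscle_id          # (S, H, W) uint8
        self.muscles = tuple(muscles)
        self.bias_field = bias_field        # (H, W) float64, same every slice
        self.geometry = geometry

    def class_counts(self, slice_index: int) -> dict[str, int]:
        cm = self.class_map[slice_index]
        return {
            name: int((cm == code).sum()) for code, name in anatomy.CLASS_NAMES.items()
        }

    def muscle_counts(self, slice_index: int, muscle: str) -> tuple[int, int, int]:
        """(total, muscle-tissue, IntraMAT) pixel counts for one muscle."""
        mid = self.muscles.index(muscle) + 1
        sel = self.muscle_id[slice_index] == mid
        cm = self.class_map[slice_index]
        n_mus = int((sel & (cm == anatomy.MUSCLE)).sum())
        n_fat = int((sel & (cm == anatomy.INTRAMAT)).sum())
        return n_mus + n_fat, n_mus, n_fat

    def csa_table(self) -> pd.DataFrame:
        """Exact per-slice CSA table (cm^2) for muscles and global classes."""
        px_area = self.geometry.pixel_area_cm2
        rows = []
        for s in range(self.class_map.shape[0]):
            for m in self.muscles:
                total, n_mus, n_fat = self.muscle_counts(s, m)
                rows.append(
                    dict(slice_index=s, structure=m,
                         muscle_csa_cm2=n_mus * px_area,
                         intramat_csa_cm2=n_fat * px_area)
                )
            counts = self.class_counts(s)
            for structure, key in (("InterMAT", "InterMAT"), ("SAT", "SAT"),
                                   ("femur", "femur"), ("unassigned", "unassigned")):
                rows.append(
                    dict(slice_index=s, structure=structure,
                         muscle_csa_cm2=0.0,
                         intramat_csa_cm2=0.0,
                         class_csa_cm2=counts[key] * px_area)
                )
        return pd.DataFrame(rows)

    def volumes(self) -> pd.DataFrame:
        """Exact volumes (cm^3) per structure, including group aggregates."""
        e_cm = self.geometry.slice_spacing_cm
        px_area = self.geometry.pixel_area_cm2
        n_slices = self.class_map.shape[0]
        rows = []
        per_muscle = {}
        for m in self.muscles:
            v_mus = v_fat = 0.0
            for s in range(n_slices):
                _, n_mus, n_fat = self.muscle_counts(s, m)
                v_mus += e_cm * n_mus * px_area
                v_fat += e_cm * n_fat * px_area
            per_muscle[m] = (v_mus, v_fat)
            rows.append(dict(structure=m, muscle_volume_cm3=v_mus, intramat_volume_cm3=v_fat))
        for group, members in anatomy.AGGREGATES.items():
            present = [m for m in members if m in per_muscle]
            if not present:
                continue
            rows.append(dict(
                structure=group,
                muscle_volume_cm3=sum(per_muscle[m][0] for m in present),
                intramat_volume_cm3=sum(per_muscle[m][1] for m in present),
            ))
        for structure, code in (("InterMAT", anatomy.INTERMAT), ("SAT", anatomy.SAT)):
            vol = sum(
                e_cm * int((self.class_map[s] == code).sum()) * px_area
                for s in range(n_slices)
            )
            rows.append(dict(structure=structure, class_volume_cm3=vol))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default geometry construction

def _sector_polygon(center, semi_axes, theta0, theta1, r_in, r_out, n_arc=9):
    """Wedge between two radii of the (scaled) fascia ellipse."""
    cx, cy = center
    ax, ay = semi_axes
    t_out = np.linspace(theta0, theta1, n_arc)
    t_in = t_out[::-1]
    xs = np.concatenate([cx + r_out * ax * np.cos(t_out), cx + r_in * ax * np.cos(t_in)])
    ys = np.concatenate([cy + r_out * ay * np.sin(t_out), cy + r_in * ay * np.sin(t_in)])
    return np.column_stack([xs, ys])


def default_phantom_spec(
    muscles=anatomy.MUSCLES,
    n_slices: int = 8,
    intramat_fraction=0.10,
    intermat_fraction: float = 0.15,
    noise_sd: float = DEFAULT_NOISE_SD,
    bias_coeffs=DEFAULT_BIAS_COEFFS,
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """Build a spec with wedge-shaped compartments for the named muscles.

    ``intramat_fraction`` may be a scalar (applied to every muscle) or a
    per-muscle dict.  Compartments are annular sectors between 34% and 88%
    of the fascia radius with small angular margins, leaving InterMAT space
    between them and around the femur.
    """
    muscles = tuple(muscles)
    for m in muscles:
        if m not in anatomy.MUSCLES:
            raise GeometryError(f"unknown muscle name {m!r}")
    base = PhantomSpec()
    center, semi = base.fascia_ellipse
    k = len(muscles)
    if k < 1:
        raise GeometryError("need at least one muscle compartment")
    margin = 0.06  # radians trimmed from each sector edge
    compartments = {}
    for i, name in enumerate(muscles):
        t0 = 2.0 * np.pi * i / k + margin
        t1 = 2.0 * np.pi * (i + 1) / k - margin
        if t1 <= t0:
            raise GeometryError("too many compartments for the angular margins")
        compartments[name] = _sector_polygon(center, semi, t0, t1, 0.34, 0.88)
    if np.isscalar(intramat_fraction):
        fractions = {m: float(intramat_fraction) for m in muscles}
    else:
        fractions = {m: float(intramat_fraction[m]) for m in muscles}
    spec = dataclasses.replace(
        base,
        n_slices=n_slices,
        muscle_compartments=compartments,
        intramat_fractions=fractions,
        intermat_fraction=float(intermat_fraction),
        noise_sd=float(noise_sd),
        bias_coeffs=tuple(bias_coeffs),
        seed=int(seed),
        **overrides,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# rendering

def bias_field_from_coeffs(coeffs, shape, clamp=BIAS_CLAMP) -> np.ndarray:
    """Second-order polynomial multiplicative field over normalised coords."""
    c0, c1, c2, c3, c4, c5 = coeffs
    h, w = shape
    v = np.linspace(-1.0, 1.0, h)[:, None]  # row direction
    u = np.linspace(-1.0, 1.0, w)[None, :]  # column direction
    field = c0 + c1 * u + c2 * v + c3 * u ** 2 + c4 * u * v + c5 * v ** 2
    field = np.clip(field, clamp[0], clamp[1])
    if (field <= 0).any():
        raise ModelError("bias field must be strictly positive")
    return field


def _speckle(rng, mask: np.ndarray, fraction: float) -> np.ndarray:
    """Select round(fraction * n) pixels of ``mask``, uniformly at random."""
    idx = np.flatnonzero(mask)
    n = int(round(fraction * idx.size))
    out = np.zeros(mask.shape, dtype=bool)
    if n > 0:
        chosen = rng.choice(idx, size=n, replace=False)
        out.flat[chosen] = True
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[AxialImageStack, GroundTruth]:
    """Render a phantom stack and its exact ground truth.

    Raises :class:`GeometryError` for overlapping or out-of-fascia muscle
    polygons and :class:`ModelError` for an invalid intensity model.
    """
    spec.validate()
    shape = spec.shape
    muscles = tuple(spec.muscle_compartments)

    body = polygon_mask(ellipse_polygon(*spec.outer_ellipse), shape)
    fascia = polygon_mask(ellipse_polygon(*spec.fascia_ellipse), shape)
    # rasterised from the same 64-gon the outline stand-in uses, so the
    # generator's partition matches the pipeline's exactly
    fc, fr = spec.femur_disk
    femur = polygon_mask(ellipse_polygon(fc, (fr, fr)), shape)
    if not (fascia <= body).all():
        raise GeometryError("fascia ellipse extends outside the outer (skin) ellipse")
    if not (femur <= fascia).all():
        raise GeometryError("femur disk extends outside the fascia ellipse")

    muscle_masks = {}
    occupied = femur.copy()
    for name, poly in spec.muscle_compartments.items():
        m = polygon_mask(poly, shape)
        if not (m <= fascia).all():
            raise GeometryError(f"muscle {name} extends outside the fascia ellipse")
        if (m & occupied).any():
            raise GeometryError(f"muscle {name} overlaps another structure")
        occupied |= m
        muscle_masks[name] = m

    gap = fascia & ~occupied

    rng = np.random.default_rng(spec.seed)
    n_sl, h, w = spec.n_slices, *shape
    class_map = np.zeros((n_sl, h, w), dtype=np.uint8)
    muscle_id = np.zeros((n_sl, h, w), dtype=np.uint8)
    bias = bias_field_from_coeffs(spec.bias_coeffs, shape, spec.bias_clamp)

    means = {
        anatomy.BACKGROUND: 0.0,
        anatomy.MUSCLE: spec.muscle_mean,
        anatomy.INTRAMAT: spec.fat_mean,
        anatomy.INTERMAT: spec.fat_mean,
        anatomy.SAT: spec.fat_mean,
        anatomy.FEMUR_CLASS: spec.femur_mean,
    }

    data = np.empty((n_sl, h, w), dtype=np.float32)
    for s in range(n_sl):
        cm = np.zeros(shape, dtype=np.uint8)
        mid = np.zeros(shape, dtype=np.uint8)
        cm[body] = anatomy.SAT
        cm[gap] = anatomy.MUSCLE          # within-fascia tissue outside compartments
        cm[femur] = anatomy.FEMUR_CLASS
        for i, name in enumerate(muscles, start=1):
            msk = muscle_masks[name]
            cm[msk] = anatomy.MUSCLE
            mid[msk] = i
            fat = _speckle(rng, msk, spec.intramat_fractions.get(name, 0.0))
            cm[fat] = anatomy.INTRAMAT
        inter = _speckle(rng, gap, spec.intermat_fraction)
        cm[inter] = anatomy.INTERMAT
        class_map[s] = cm
        muscle_id[s] = mid

        template = np.zeros(shape, dtype=float)
        for code, mean in means.items():
            template[cm == code] = mean
        signal = template * bias
        if spec.noise_sd > 0:
            if spec.noise_model == "gaussian":
                signal = signal + rng.normal(0.0, spec.noise_sd, shape)
            else:  # rician: magnitude of complex Gaussian perturbation
                re = signal + rng.normal(0.0, spec.noise_sd, shape)
                im = rng.normal(0.0, spec.noise_sd, shape)
                signal = np.hypot(re, im)
        data[s] = np.clip(signal, 0.0, None)

    stack = AxialImageStack(data=data, geometry=spec.geometry)
    truth = GroundTruth(class_map, muscle_id, muscles, bias, spec.geometry)
    return stack, truth


# ---------------------------------------------------------------------------
# longitudinal cohorts

GROUPS = ("TR", "CTR")
SESSIONS = ("before", "after")


@dataclass(frozen=True)
class CohortDesign:
    """Two-group before/after design with per-structure volume effects.

    ``effect_model`` maps group -> {structure: (mean change cm^3, between-
    subject sd cm^3)} for muscle-tissue volume; structure may be a single
    muscle, a muscle group (QF/HM/AD/whole thigh), "SAT" or "InterMAT".
    ``baseline_cv`` is the coefficient of variation of the per-subject
    baseline scale factor (between-subject size variation).
    """

    n_per_group: int = 8
    effect_model: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    baseline_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise DesignError("need at least 2 subjects per group")
        if self.baseline_cv < 0:
            raise DesignError("baseline CV must be non-negative")
        for group, effects in self.effect_model.items():
            if group not in GROUPS:
                raise DesignError(f"unknown group {group!r}; expected one of {GROUPS}")
            for structure, (_, sd) in effects.items():
                if sd < 0:
                    raise DesignError(f"negative sd for {group}/{structure}")


@dataclass
class SubjectScan:
    subject: str
    group: str
    session: str
    stack: AxialImageStack | None = None
    ground_truth: GroundTruth | None = None
    render_spec: PhantomSpec | None = None  # spec actually rendered, if any


@dataclass
class Cohort:
    design: CohortDesign
    scans: list[SubjectScan]
    volume_table: pd.DataFrame  # analytic truth: subject, group, session, structure, volumes


def _polygon_area(vertices) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _template_volumes(template: PhantomSpec) -> dict[str, dict[str, float]]:
    """Analytic baseline volumes (cm^3) per structure from polygon areas."""
    geom = template.geometry
    px_area = geom.pixel_area_cm2
    length = geom.slice_spacing_cm * template.n_slices
    out = {}
    for name, poly in template.muscle_compartments.items():
        total = _polygon_area(poly) * px_area * length
        frac = template.intramat_fractions.get(name, 0.0)
        out[name] = {"muscle": total * (1.0 - frac), "intramat": total * frac}
    for group, members in anatomy.AGGREGATES.items():
        present = [m for m in members if m in out]
        if present:
            out[group] = {
                "muscle": sum(out[m]["muscle"] for m in present),
                "intramat": sum(out[m]["intramat"] for m in present),
            }
    (ocx, ocy), (oax, oay) = template.outer_ellipse
    (fcx, fcy), (fax, fay) = template.fascia_ellipse
    ring_px = np.pi * (oax * oay - fax * fay)
    out["SAT"] = {"class": ring_px * px_area * length}
    femur_px = np.pi * template.femur_disk[1] ** 2
    gap_px = np.pi * fax * fay - femur_px - sum(
        _polygon_area(p) for p in template.muscle_compartments.values()
    )
    out["InterMAT"] = {"class": gap_px * template.intermat_fraction * px_area * length}
    return out


def _resolve_members(structure: str, template: PhantomSpec) -> list[str]:
    if structure in anatomy.AGGREGATES:
        members = [m for m in anatomy.AGGREGATES[structure] if m in template.muscle_compartments]
        if not members:
            raise DesignError(f"effect on {structure} but no member muscle in the template")
        return members
    if structure in template.muscle_compartments or structure in ("SAT", "InterMAT"):
        return [structure]
    raise DesignError(f"effect on unknown structure {structure!r}")


def generate_cohort(
    design: CohortDesign,
    template: PhantomSpec | None = None,
    render: bool = False,
) -> Cohort:
    """Draw a before/after cohort from the effect model.

    The returned ``volume_table`` carries the drawn (exact) per-subject true
    volumes.  With ``render=True`` each scan also gets an image stack whose
    compartment geometry is rescaled toward the drawn volumes (subject to
    pixelation) together with that image's own pixel-exact GroundTruth.
    """
    design.validate()
    if template is None:
        template = default_phantom_spec()
    base = _template_volumes(template)
    ss = np.random.SeedSequence(design.seed)
    rows = []
    scans: list[SubjectScan] = []
    subject_seeds = ss.spawn(len(GROUPS) * design.n_per_group)
    idx = 0
    for group in GROUPS:
        effects = design.effect_model.get(group, {})
        for j in range(design.n_per_group):
            subject = f"{group}{j + 1:02d}"
            child = subject_seeds[idx]
            idx += 1
            rng = np.random.default_rng(child)
            f_subj = max(0.5, 1.0 + design.baseline_cv * rng.standard_normal())

            # per-muscle volume scale factors, before -> after
            before = {
                s: {k: v * f_subj for k, v in comp.items()} for s, comp in base.items()
            }
            after = {s: dict(comp) for s, comp in before.items()}
            muscle_scale: dict[str, float] = {}
            for structure, (mean, sd) in effects.items():
                delta = mean + sd * rng.standard_normal()
                members = _resolve_members(structure, template)
                if structure in ("SAT", "InterMAT"):
                    after[structure]["class"] = max(
                        0.0, before[structure]["class"] + delta
                    )
                    continue
                tot = sum(before[m]["muscle"] for m in members)
                for m in members:
                    share = delta * before[m]["muscle"] / tot
                    new = max(0.0, before[m]["muscle"] + share)
                    after[m]["muscle"] = new
                    muscle_scale[m] = (new + after[m]["intramat"]) / (
                        before[m]["muscle"] + before[m]["intramat"]
                    )
            for agg, members in anatomy.AGGREGATES.items():
                present = [m for m in members if m in template.muscle_compartments]
                if present:
                    after[agg] = {
                        "muscle": sum(after[m]["muscle"] for m in present),
                        "intramat": sum(after[m]["intramat"] for m in present),
                    }

            for session, vols in (("before", before), ("after", after)):
                for structure, comp in vols.items():
                    rows.append(dict(
                        subject=subject, group=group, session=session,
                        structure=structure,
                        muscle_volume_cm3=comp.get("muscle", np.nan),
                        intramat_volume_cm3=comp.get("intramat", np.nan),
                        class_volume_cm3=comp.get("class", np.nan),
                    ))
                scan = SubjectScan(subject=subject, group=group, session=session)
                if render:
                    spec = _scaled_spec(
                        template, f_subj,
                        muscle_scale if session == "after" else {},
                        seed=int(child.generate_state(1)[0] % (2 ** 31)),
                    )
                    scan.stack, scan.ground_truth = generate_phantom(spec)
                    scan.render_spec = spec
                scans.append(scan)
    table = pd.DataFrame(rows)
    return Cohort(design=design, scans=scans, volume_table=table)


def _scaled_spec(template, f_subj, muscle_scale, seed):
    """Rescale compartment polygons radially about the fascia center.

    Scaling in normalised elliptic coordinates preserves each sector's
    angular extent, so rescaled compartments stay pairwise disjoint; the
    normalised radius is clamped away from the femur and the fascia.
    """
    (cx, cy), (ax, ay) = template.fascia_ellipse
    (fx, fy), fr = template.femur_disk
    t = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    femur_r = np.hypot((fx + fr * np.cos(t) - cx) / ax,
                       (fy + fr * np.sin(t) - cy) / ay).max()
    r_min, r_max = femur_r + 0.02, 0.97
    compartments = {}
    for name, poly in template.muscle_compartments.items():
        factor = f_subj * muscle_scale.get(name, 1.0)
        lin = np.sqrt(max(factor, 0.0))
        v = np.asarray(poly, dtype=float)
        u = (v[:, 0] - cx) / ax
        w = (v[:, 1] - cy) / ay
        r = np.hypot(u, w)
        scale = np.clip(r * lin, r_min, r_max) / np.where(r > 0, r, 1.0)
        compartments[name] = np.column_stack([cx + u * scale * ax,
                                              cy + w * scale * ay])
    return dataclasses.replace(template, muscle_compartments=compartments, seed=seed)
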