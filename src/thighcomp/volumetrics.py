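"""Pixel counts -> cross-sectional areas -> volumes -> derived quantities.

The conversion chain is deliberately simple and exact:

* CSA (cm^2) = pixel count x (pixel spacing in cm)^2, with pixel spacing =
  field of view / matrix size (1.40625 mm on both axes at the default
  450 x 270 mm / 320 x 192 geometry);
* volume (cm^3) = sum over analysed slices of e_i x CSA_i, where e_i is the
  center-to-center slice spacing in cm (default 2.4 cm: 12 mm slice
  thickness plus 12 mm gap);
* IntraMAT content (%) = IntraMAT volume / (muscle tissue volume +
  IntraMAT volume) x 100, computed per subject before any averaging;
* muscle groups are sums of their member muscles: QF = RF+VL+VI+VM,
  HM = BFs+BFl+ST+SM, AD = AL+AM+AB+Sar+Gr, whole thigh = QF+HM+AD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anatomy
from .errors import AggregationError, InputError, UndefinedContentError

CSA_COLUMNS = ["subject", "session", "slice_index", "structure",
               "muscle_csa_cm2", "intramat_csa_cm2"]
VOLUME_COLUMNS = ["subject", "session", "structure", "muscle_volume_cm3",
                  "intramat_volume_cm3", "intermat_volume_cm3", "sat_volume_cm3",
                  "intramat_content_pct"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Field of view, matrix and slice spacing of an axial acquisition.

    ``slice_spacing_mm`` is the center-to-center distance used for volume
    integration; when not given it defaults to slice thickness + gap
    (24 mm at the default acquisition).
    """

    fov_mm: tuple[float, float] = (450.0, 270.0)
    matrix_px: tuple[int, int] = (320, 192)
    slice_thickness_mm: float = 12.0
    interslice_gap_mm: float = 12.0
    slice_spacing_mm: float | None = None

    def __post_init__(self):
        if min(self.fov_mm) <= 0 or min(self.matrix_px) <= 0:
            raise InputError("field of view and matrix must be positive")
        if self.slice_thickness_mm <= 0 or self.interslice_gap_mm < 0:
            raise InputError("slice thickness must be positive, gap non-negative")
        if self.slice_spacing_mm is not None and self.slice_spacing_mm <= 0:
            raise InputError("slice spacing must be positive")

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return (self.fov_mm[0] / self.matrix_px[0], self.fov_mm[1] / self.matrix_px[1])

    @property
    def pixel_area_cm2(self) -> float:
        sy, sx = self.pixel_spacing_mm
        return (sy / 10.0) * (sx / 10.0)

    @property
    def effective_slice_spacing_mm(self) -> float:
        if self.slice_spacing_mm is not None:
            return self.slice_spacing_mm
        return self.slice_thickness_mm + self.interslice_gap_mm

    @property
    def slice_spacing_cm(self) -> float:
        return self.effective_slice_spacing_mm / 10.0


def csa_from_pixels(pixel_count, geom: AcquisitionGeometry) -> float:
    """CSA in cm^2 from a pixel count: count x (FOV/matrix)^2."""
    arr = np.asarray(pixel_count, dtype=float)
    if (arr < 0).any():
        raise InputError("pixel count must be non-negative")
    result = arr * geom.pixel_area_cm2
    return float(result) if result.ndim == 0 else result


def integrate_volume(csas, geom: AcquisitionGeometry) -> float:
    """Volume in cm^3 as sum of e_i x CSA_i over the analysed slices."""
    arr = np.asarray(csas, dtype=float)
    if arr.size == 0:
        raise InputError("need at least one slice CSA")
    if not np.isfinite(arr).all():
        raise InputError("CSAs must be finite")
    return float(geom.slice_spacing_cm * arr.sum())


def intramat_content(muscle_vol: float, intramat_vol: float) -> float:
    """IntraMAT volume as a percentage of (muscle + IntraMAT) volume."""
    if muscle_vol < 0 or intramat_vol < 0:
        raise InputError("volumes must be non-negative")
    total = muscle_vol + intramat_vol
    if total == 0:
        raise UndefinedContentError("muscle and IntraMAT volumes are both zero")
    return 100.0 * intramat_vol / total


def percent_change(before: float, after: float) -> float:
    """100 x (after - before) / before; ``before`` must be positive."""
    if before <= 0:
        raise InputError("baseline value must be positive")
    return 100.0 * (after - before) / before


def aggregate_structures(table: pd.DataFrame,
                         aggregates: list[str] | None = None) -> pd.DataFrame:
    """Append muscle-group rows (sums of members) to a CSA table.

    By default every aggregate (QF, HM, AD, whole thigh) whose member
    muscles are all present in the table is appended; aggregates with no
    complete member set are skipped, so partial-thigh tables remain usable.
    Passing an explicit ``aggregates`` list enforces completeness: a
    missing member muscle raises :class:`AggregationError` naming it.
    """
    required = {"subject", "session", "slice_index", "structure",
                "muscle_csa_cm2", "intramat_csa_cm2"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise InputError(f"CSA table missing columns: {sorted(missing_cols)}")
    base = table[~table["structure"].isin(anatomy.AGGREGATES)]
    present_structures = set(base["structure"])
    if aggregates is None:
        wanted = [g for g, members in anatomy.AGGREGATES.items()
                  if set(members) <= present_structures]
    else:
        unknown = [g for g in aggregates if g not in anatomy.AGGREGATES]
        if unknown:
            raise InputError(f"unknown aggregates: {unknown}")
        wanted = list(aggregates)
    out = [base]
    keys = ["subject", "session", "slice_index"]
    for group in wanted:
        members = anatomy.AGGREGATES[group]
        sub = base[base["structure"].isin(members)]
        for (subject, session, sl), cell in sub.groupby(keys):
            present = set(cell["structure"])
            absent = [m for m in members if m not in present]
            if absent:
                raise AggregationError(
                    f"{group} incomplete for subject={subject} session={session} "
                    f"slice={sl}: missing {absent[0]}"
                )
        if sub.empty:
            raise AggregationError(f"{group}: no member muscle present")
        agg = (sub.groupby(keys, as_index=False)[["muscle_csa_cm2", "intramat_csa_cm2"]]
               .sum())
        agg["structure"] = group
        out.append(agg)
    result = pd.concat(out, ignore_index=True)
    return result[[c for c in CSA_COLUMNS if c in result.columns]
                  + [c for c in result.columns if c not in CSA_COLUMNS]]


def volume_table(
    csa_table: pd.DataFrame,
    geom: AcquisitionGeometry,
    slice_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Integrate a per-slice CSA table into a per-subject volume table.

    ``slice_range`` selects the analysed slices as a half-open [start, stop)
    interval of slice indices; by default every slice present is used.
    Structure rows named "InterMAT"/"SAT" (carrying ``class_csa_cm2``) are
    integrated into the dedicated volume columns of the "whole thigh" row
    and their own rows; IntraMAT content is computed row-wise.
    """
    tab = csa_table
    if slice_range is not None:
        lo, hi = slice_range
        tab = tab[(tab["slice_index"] >= lo) & (tab["slice_index"] < hi)]
        if tab.empty:
            raise InputError(f"no slices in range [{lo}, {hi})")
    e = geom.slice_spacing_cm
    rows = []
    for (subject, session, structure), cell in tab.groupby(
        ["subject", "session", "structure"]
    ):
        row = dict(subject=subject, session=session, structure=structure,
                   muscle_volume_cm3=np.nan, intramat_volume_cm3=np.nan,
                   intermat_volume_cm3=np.nan, sat_volume_cm3=np.nan,
                   intramat_content_pct=np.nan)
        if structure in ("InterMAT", "SAT"):
            vol = e * cell["class_csa_cm2"].sum()
            key = "intermat_volume_cm3" if structure == "InterMAT" else "sat_volume_cm3"
            row[key] = vol
        elif structure in ("femur", "unassigned"):
            continue
        else:
            v_mus = e * cell["muscle_csa_cm2"].sum()
            v_fat = e * cell["intramat_csa_cm2"].sum()
            row["muscle_volume_cm3"] = v_mus
            row["intramat_volume_cm3"] = v_fat
            if v_mus + v_fat > 0:
                row["intramat_content_pct"] = intramat_content(v_mus, v_fat)
        rows.append(row)
    return pd.DataFrame(rows, columns=VOLUME_COLUMNS)
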