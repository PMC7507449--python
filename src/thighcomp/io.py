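"""File formats, run configuration, and pipeline orchestration.

Image stacks and label maps travel as NIfTI (spacing carried in the
header); traced outlines as GeoJSON-style feature collections (one polygon
feature per structure per slice); tables as CSV with a units row directly
under the header.  A full run — simulate or load, correct, segment,
integrate volumes, statistics — is driven by a single YAML config and a
single seed, and emits a manifest with the config hash and per-file
checksums so any run can be reproduced and audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import anatomy, segmentation, stats, synthetic, volumetrics
from .bias import N3Params, correct_stack
from .errors import ConfigError, GeometryError, NamingError
from .segmentation import SliceOutlineSet
from .synthetic import AxialImageStack, CohortDesign, default_phantom_spec
from .volumetrics import AcquisitionGeometry

log = logging.getLogger("thighcomp.pipeline")

VOLUME_UNITS = {"muscle_volume_cm3": "cm^3", "intramat_volume_cm3": "cm^3",
                "intermat_volume_cm3": "cm^3", "sat_volume_cm3": "cm^3",
                "intramat_content_pct": "%"}
CSA_UNITS = {"muscle_csa_cm2": "cm^2", "intramat_csa_cm2": "cm^2",
             "class_csa_cm2": "cm^2"}


# ---------------------------------------------------------------------------
# NIfTI

def _affine(geom: AcquisitionGeometry) -> np.ndarray:
    sy, sx = geom.pixel_spacing_mm
    return np.diag([sx, sy, geom.effective_slice_spacing_mm, 1.0])


def write_stack(stack: AxialImageStack, path) -> None:
    # store as (cols, rows, slices) so the affine spacing order matches
    data = np.transpose(stack.data, (2, 1, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(stack.geometry)), str(path))


def read_stack(path, geom: AcquisitionGeometry | None = None) -> AxialImageStack:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(np.float32)
    if geom is None:
        sx, sy, sz = img.header.get_zooms()[:3]
        h, w = data.shape[1], data.shape[2]
        geom = AcquisitionGeometry(fov_mm=(sy * h, sx * w), matrix_px=(h, w),
                                   slice_thickness_mm=sz, interslice_gap_mm=0.0,
                                   slice_spacing_mm=sz)
    return AxialImageStack(data=data, geometry=geom)


def write_labels(class_map: np.ndarray, geom: AcquisitionGeometry, path) -> None:
    """Integer label NIfTI plus a JSON legend next to it."""
    data = np.transpose(class_map, (2, 1, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(geom)), str(path))
    legend = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii[.gz]
    with open(f"{legend}_legend.json", "w") as fh:
        json.dump({str(k): v for k, v in anatomy.CLASS_NAMES.items()}, fh, indent=1)


# ---------------------------------------------------------------------------
# outlines (GeoJSON-style)

def write_outlines(outline_sets, path) -> None:
    features = []
    for oset in outline_sets:
        for name, verts in oset.polygons.items():
            features.append({
                "type": "Feature",
                "properties": {"slice_index": int(oset.slice_index), "name": name},
                "geometry": {"type": "Polygon",
                             "coordinates": [np.asarray(verts, dtype=float).tolist()]},
            })
    with open(str(path), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_outlines(path) -> dict[int, SliceOutlineSet]:
    """Parse and validate outline polygons; keyed by slice index.

    Unknown structure names raise :class:`NamingError` listing the valid
    names; malformed polygons raise :class:`GeometryError` with their
    location.
    """
    with open(str(path)) as fh:
        doc = json.load(fh)
    per_slice: dict[int, dict[str, np.ndarray]] = {}
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {})
        name = props.get("name")
        sl = props.get("slice_index")
        if name not in anatomy.OUTLINE_NAMES:
            raise NamingError(name, anatomy.OUTLINE_NAMES)
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon" or not geom.get("coordinates"):
            raise GeometryError(f"feature {i} ({name}, slice {sl}): not a polygon")
        verts = np.asarray(geom["coordinates"][0], dtype=float)
        n = len(verts) - (1 if len(verts) > 1 and np.allclose(verts[0], verts[-1]) else 0)
        if verts.ndim != 2 or verts.shape[1] != 2 or n < 3:
            raise GeometryError(
                f"feature {i} ({name}, slice {sl}): polygon needs >= 3 "
                f"distinct vertices, got {verts.shape}"
            )
        per_slice.setdefault(int(sl), {})[name] = verts
    return {sl: SliceOutlineSet(slice_index=sl, polygons=polys)
            for sl, polys in sorted(per_slice.items())}


# ---------------------------------------------------------------------------
# CSV with units row

def write_table(df: pd.DataFrame, path, units: dict[str, str]) -> None:
    """CSV whose second line gives the unit of each column."""
    unit_row = ",".join(
        ["#units"] + [units.get(c, "") for c in df.columns[1:]]
    ) if len(df.columns) else "#units"
    with open(str(path), "w") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(unit_row + "\n")
        df.to_csv(fh, index=False, header=False)


def read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    with open(str(path)) as fh:
        header = fh.readline().strip().split(",")
        units_line = fh.readline().strip().split(",")
        df = pd.read_csv(fh, names=header)
    units = {c: u for c, u in zip(header[1:], units_line[1:]) if u}
    return df, units


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    out_dir: str
    seed: int = 0
    # simulate mode (images_path is None) or load mode
    images_path: str | None = None
    outlines_path: str | None = None
    n_per_group: int = 2
    n_slices: int = 4
    muscles: tuple[str, ...] = anatomy.MUSCLES
    intramat_fraction: float = 0.10
    intermat_fraction: float = 0.15
    noise_sd: float = 5.0
    effect_model: dict = field(default_factory=dict)
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    n3: N3Params = field(default_factory=N3Params)
    threshold_bins: int = segmentation.DEFAULT_BINS
    threshold_smooth_sigma: float = segmentation.DEFAULT_SMOOTH_SIGMA
    threshold_repetitions: int = segmentation.DEFAULT_REPETITIONS
    slice_range: tuple[int, int] | None = None
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(str(path)) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        if "geometry" in doc and isinstance(doc["geometry"], dict):
            g = doc["geometry"]
            for key in ("fov_mm", "matrix_px"):
                if key in g:
                    g[key] = tuple(g[key])
            doc["geometry"] = AcquisitionGeometry(**g)
        if "n3" in doc and isinstance(doc["n3"], dict):
            doc["n3"] = N3Params(**doc["n3"])
        if "muscles" in doc:
            doc["muscles"] = tuple(doc["muscles"])
        if "slice_range" in doc and doc["slice_range"] is not None:
            doc["slice_range"] = tuple(doc["slice_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in doc:
            raise ConfigError("config missing required field: out_dir")
        return cls(**doc)

    def validate(self) -> None:
        load_mode = self.images_path is not None
        if load_mode:
            if self.outlines_path is None:
                raise ConfigError("load mode requires field: outlines_path")
            for fld in ("images_path", "outlines_path"):
                p = getattr(self, fld)
                if not Path(p).exists():
                    raise ConfigError(f"{fld}: path does not exist: {p}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        self.n3.validate()

    def canonical(self) -> str:
        doc = dataclasses.asdict(self)
        return json.dumps(doc, sort_keys=True, default=str)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    started: str
    finished: str
    outputs: dict[str, str]  # relative path -> sha256
    stages: list[str]

    def write(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(str(path), "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline

def _segment_stack(data, outlines_by_slice, config, subject, session, seed):
    rows, thr_rows = [], []
    for s in range(data.shape[0]):
        oset = outlines_by_slice.get(s) or outlines_by_slice.get(0)
        if oset is None:
            raise ConfigError(f"no outline set for slice {s}")
        rois = segmentation.place_rois(data[s], oset)
        thr = segmentation.compute_threshold(
            data[s], rois, n_repetitions=config.threshold_repetitions,
            seed=seed + s, bins=config.threshold_bins,
            smooth_sigma=config.threshold_smooth_sigma,
        )
        labels = segmentation.classify_slice(data[s], oset, thr.threshold)
        rows.extend(segmentation.label_map_to_csa_rows(
            labels, s, config.geometry, subject=subject, session=session))
        thr_rows.append(dict(subject=subject, session=session, slice_index=s,
                             threshold=thr.threshold,
                             repetitions=len(thr.repetition_thresholds)))
    return rows, thr_rows


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate-or-load -> correct -> segment -> volumes -> stats.

    Validates the configuration before any computation; each stage failure
    propagates with the stage named in the log.  Returns the manifest after
    writing all tables under ``config.out_dir``.
    """
    config.validate()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = []

    log.info("run: seed=%d out=%s", config.seed, out)
    scans: list[tuple[str, str, str, np.ndarray, dict[int, SliceOutlineSet]]] = []
    if config.images_path is None:
        stages.append("simulate")
        spec = default_phantom_spec(
            muscles=config.muscles, n_slices=config.n_slices,
            intramat_fraction=config.intramat_fraction,
            intermat_fraction=config.intermat_fraction,
            noise_sd=config.noise_sd, seed=config.seed,
        )
        design = CohortDesign(n_per_group=config.n_per_group,
                              effect_model=config.effect_model, seed=config.seed)
        log.info("simulate: n_per_group=%d n_slices=%d noise_sd=%.3g",
                 design.n_per_group, spec.n_slices, spec.noise_sd)
        cohort = synthetic.generate_cohort(design, spec, render=True)
        for scan in cohort.scans:
            # outlines follow each scan's own (rescaled) geometry
            oset = segmentation.outlines_from_spec(scan.render_spec or spec)
            scans.append((scan.subject, scan.group, scan.session,
                          scan.stack.data, {0: oset}))
        write_table(cohort.volume_table, out / "true_volumes.csv",
                    {"muscle_volume_cm3": "cm^3", "intramat_volume_cm3": "cm^3",
                     "class_volume_cm3": "cm^3"})
    else:
        stages.append("load")
        stack = read_stack(config.images_path, config.geometry)
        outlines = read_outlines(config.outlines_path)
        scans.append(("subject01", "TR", "before", stack.data, outlines))

    stages.append("correct")
    n3 = config.n3
    log.info("correct: tol=%g max_iter=%d field_distance=%g mm fwhm=%g wiener=%g",
             n3.end_tolerance, n3.max_iterations, n3.field_distance_mm,
             n3.kernel_fwhm, n3.wiener_noise)
    stages.append("segment")
    all_rows, all_thr, groups = [], [], {}
    for subject, group, session, data, outl in scans:
        corrected, _ = correct_stack(data, n3, config.geometry.pixel_spacing_mm)
        rows, thr_rows = _segment_stack(corrected, outl, config, subject, session,
                                        seed=config.seed)
        all_rows.extend(rows)
        all_thr.extend(thr_rows)
        groups[subject] = group

    stages.append("volumes")
    csa = volumetrics.aggregate_structures(pd.DataFrame(all_rows))
    vols = volumetrics.volume_table(csa, config.geometry, config.slice_range)
    vols.insert(2, "group", vols["subject"].map(groups))
    write_table(csa, out / "csa_per_slice.csv", CSA_UNITS)
    write_table(vols, out / "volumes.csv", VOLUME_UNITS)
    write_table(pd.DataFrame(all_thr), out / "thresholds.csv",
                {"threshold": "intensity"})

    stages.append("stats")
    if vols["group"].nunique() >= 2 and vols["subject"].nunique() >= 4:
        report = stats.analyze_cohort(vols, alpha=config.alpha)
        for name, df in report.items():
            write_table(df, out / f"stats_{name}.csv", {})

    finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs = {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
    manifest = RunManifest(
        config_hash=hashlib.sha256(config.canonical().encode()).hexdigest(),
        package_version=_version(),
        seed=config.seed, started=started, finished=finished,
        outputs=outputs, stages=stages,
    )
    manifest.write(out / "manifest.json")
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("thighcomp")
    except Exception:
        return "unknown"
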