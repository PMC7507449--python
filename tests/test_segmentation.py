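"""Threshold isolation and tissue classification contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thighcomp as tc
from thighcomp import anatomy
from thighcomp.errors import BimodalityError, GeometryError, InputError
from thighcomp.segmentation import (
    RoiSample,
    SliceOutlineSet,
    classify_muscle_pixels,
    classify_slice,
    compute_threshold,
    outlines_from_spec,
    place_rois,
    sat_csa_by_subtraction,
)


def _sample_image(rng, m1, s1, m2, s2, side=120):
    """Left half muscle-mode, right half fat-mode; ROIs covering each."""
    img = np.zeros((side, 2 * side))
    img[:, :side] = rng.normal(m1, s1, (side, side))
    img[:, side:] = rng.normal(m2, s2, (side, side))
    r = side / 2 - 4
    rois = RoiSample(
        muscle_disks=tuple([((side / 2, side / 2), r)] * 3),
        sat_disks=tuple([((side * 1.5, side / 2), r)] * 3),
    )
    return np.abs(img), rois


def test_threshold_lands_in_valley_of_balanced_mixture(rng):
    img, rois = _sample_image(rng, 100, 5, 200, 5)
    res = compute_threshold(img, rois, seed=0)
    assert 140 <= res.threshold <= 160
    assert res.threshold == pytest.approx(np.mean(res.repetition_thresholds))


def test_degenerate_two_value_sample_threshold_strictly_between():
    img = np.zeros((60, 120))
    img[:, :60] = 100.0
    img[:, 60:] = 200.0
    rois = RoiSample(muscle_disks=tuple([((30, 30), 20)] * 3),
                     sat_disks=tuple([((90, 30), 20)] * 3))
    res = compute_threshold(img, rois, seed=0)
    assert 100 < res.threshold < 200


def test_unimodal_sample_raises_bimodality_error(rng):
    img = np.abs(rng.normal(150, 5, (60, 120)))
    rois = RoiSample(muscle_disks=tuple([((30, 30), 20)] * 3),
                     sat_disks=tuple([((90, 30), 20)] * 3))
    with pytest.raises(BimodalityError):
        compute_threshold(img, rois, seed=0)


def test_roi_outside_image_raises(rng):
    img = np.ones((32, 32))
    rois = RoiSample(muscle_disks=(((100.0, 100.0), 3),) * 3,
                     sat_disks=(((10.0, 10.0), 3),) * 3)
    with pytest.raises(GeometryError):
        compute_threshold(img, rois, seed=0)


def test_threshold_reproducible_for_fixed_seed(rng):
    img, rois = _sample_image(rng, 100, 12, 200, 12)
    a = compute_threshold(img, rois, seed=7)
    b = compute_threshold(img, rois, seed=7)
    assert a.repetition_thresholds == b.repetition_thresholds
    assert a.threshold == b.threshold


# -- pixel classification ----------------------------------------------------

# corners between pixel centers, so the polygon contains exactly the
# 10x10 block of centers (10..19 on both axes)
SQUARE = [(9.5, 9.5), (19.5, 9.5), (19.5, 19.5), (9.5, 19.5)]


def test_counts_bookkeeping_and_tie_rule():
    img = np.full((32, 32), 100.0)
    mask_rows = slice(10, 20)
    img[mask_rows, 10:20] = 100.0
    # 10 pixels above threshold
    img[10, 10:20] = 200.0
    total, muscle, fat = classify_muscle_pixels(img, SQUARE, threshold=150.0)
    assert (total, muscle, fat) == (100, 90, 10)
    # intensity exactly equal to the threshold counts as muscle
    total, muscle, fat = classify_muscle_pixels(img, SQUARE, threshold=100.0)
    assert muscle == 90 and fat == 10
    total, muscle, fat = classify_muscle_pixels(img, SQUARE, threshold=200.0)
    assert muscle == 100 and fat == 0


def test_all_below_threshold_gives_zero_intramat():
    img = np.full((32, 32), 50.0)
    total, muscle, fat = classify_muscle_pixels(img, SQUARE, threshold=100.0)
    assert fat == 0 and muscle == total == 100


def test_empty_polygon_raises():
    img = np.ones((32, 32))
    with pytest.raises(GeometryError):
        classify_muscle_pixels(img, [(0.1, 0.1), (0.2, 0.1), (0.2, 0.2)], 1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(t1=st.floats(60, 240), t2=st.floats(60, 240))
def test_threshold_monotonicity(t1, t2):
    """Raising the threshold never decreases the muscle count."""
    rng = np.random.default_rng(99)
    img = rng.uniform(50, 250, (32, 32))
    lo, hi = min(t1, t2), max(t1, t2)
    _, mus_lo, fat_lo = classify_muscle_pixels(img, SQUARE, lo)
    _, mus_hi, fat_hi = classify_muscle_pixels(img, SQUARE, hi)
    assert mus_hi >= mus_lo
    assert fat_hi <= fat_lo


# -- full-slice classification -----------------------------------------------

def test_partition_conservation_and_recovery(quad_phantom_snr20):
    spec, (stack, gt) = quad_phantom_snr20
    outl = outlines_from_spec(spec)
    labels = classify_slice(stack.data[0], outl, threshold=150.0)
    counts = labels.class_counts()
    assert sum(counts.values()) == stack.shape[0] * stack.shape[1]


def test_noiseless_classification_matches_ground_truth(quad_phantom_noiseless,
                                                       quad_spec_noiseless):
    stack, gt = quad_phantom_noiseless
    outl = outlines_from_spec(quad_spec_noiseless)
    labels = classify_slice(stack.data[0], outl, threshold=150.0)
    for m in gt.muscles:
        assert labels.muscle_counts(m) == gt.muscle_counts(0, m)
    got = labels.class_counts()
    want = gt.class_counts(0)
    for cls in ("InterMAT", "SAT", "femur"):
        assert got[cls] == want[cls]


def test_zero_intermat_phantom_yields_zero_intermat():
    spec = tc.default_phantom_spec(muscles=("RF", "VL"), n_slices=1,
                                   intermat_fraction=0.0, noise_sd=0.0, seed=6)
    stack, _ = tc.generate_phantom(spec)
    labels = classify_slice(stack.data[0], outlines_from_spec(spec), 150.0)
    assert labels.class_counts()["InterMAT"] == 0


def test_sat_direct_equals_subtraction_when_nothing_unassigned():
    # fully-fat inter-compartment space: every within-fascia pixel is
    # claimed, so the subtraction equation matches direct labelling exactly
    spec = tc.default_phantom_spec(muscles=("RF", "VL", "VI", "VM"), n_slices=1,
                                   intermat_fraction=0.0, noise_sd=0.0, seed=6)
    stack, _ = tc.generate_phantom(spec)
    img = stack.data[0].copy()
    labels = classify_slice(img, outlines_from_spec(spec), 150.0)
    c = labels.class_counts()
    total = sum(v for k, v in c.items() if k != "background")
    direct = c["SAT"] + c["unassigned"]
    by_subtraction = sat_csa_by_subtraction(
        total, c["muscle"], c["IntraMAT"], c["InterMAT"], c["femur"])
    assert direct == by_subtraction
    # and with no unassigned pixels the two SAT routes coincide exactly
    img2 = np.where(labels.class_map == anatomy.UNASSIGNED, 200.0, img)
    labels2 = classify_slice(img2, outlines_from_spec(spec), 150.0)
    c2 = labels2.class_counts()
    assert c2["unassigned"] == 0
    total2 = sum(v for k, v in c2.items() if k != "background")
    assert c2["SAT"] == sat_csa_by_subtraction(
        total2, c2["muscle"], c2["IntraMAT"], c2["InterMAT"], c2["femur"])


def test_missing_fascia_or_femur_raises(quad_phantom_snr20):
    spec, (stack, _) = quad_phantom_snr20
    outl = outlines_from_spec(spec)
    polys = {k: v for k, v in outl.polygons.items() if k != anatomy.FEMUR}
    with pytest.raises(InputError):
        classify_slice(stack.data[0], SliceOutlineSet(0, polys), 150.0)


def test_place_rois_lands_in_correct_tissues(quad_phantom_snr20):
    spec, (stack, gt) = quad_phantom_snr20
    outl = outlines_from_spec(spec)
    rois = place_rois(stack.data[0], outl)
    assert len(rois.muscle_disks) == 3 and len(rois.sat_disks) == 3
    cm = gt.class_map[0]
    for (cx, cy), _ in rois.muscle_disks:
        assert gt.muscle_id[0][int(round(cy)), int(round(cx))] > 0
    for (cx, cy), _ in rois.sat_disks:
        assert cm[int(round(cy)), int(round(cx))] == anatomy.SAT
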