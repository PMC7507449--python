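"""Thigh anatomy naming and label-map conventions shared across the pipeline.

Thirteen muscles are analysed per axial slice, aggregated into three muscle
groups plus the whole thigh:

* quadriceps femoris (QF): RF, VL, VI, VM
* hamstrings (HM): BFs, BFl, ST, SM
* hip adductors (AD): AL, AM, AB, Sar, Gr

Tissue classes follow the T1-weighted reading: muscle tissue (hypointense),
IntraMAT (adipose within a muscle's traced boundary), InterMAT (adipose deep
to the fascia but outside every muscle), SAT (adipose between fascia and
skin), femur, and within-fascia sub-threshold pixels outside every muscle
boundary, which are counted separately as "unassigned" rather than folded
into any tissue.
"""

from __future__ import annotations

MUSCLES: tuple[str, ...] = (
    "RF", "VL", "VI", "VM",          # quadriceps femoris
    "BFs", "BFl", "ST", "SM",        # hamstrings
    "AL", "AM", "AB", "Sar", "Gr",   # hip adductors
)

MUSCLE_GROUPS: dict[str, tuple[str, ...]] = {
    "QF": ("RF", "VL", "VI", "VM"),
    "HM": ("BFs", "BFl", "ST", "SM"),
    "AD": ("AL", "AM", "AB", "Sar", "Gr"),
}

WHOLE_THIGH = "whole thigh"
AGGREGATES: dict[str, tuple[str, ...]] = {**MUSCLE_GROUPS, WHOLE_THIGH: MUSCLES}

FASCIA = "fascia"
FEMUR = "femur"
OUTLINE_NAMES = frozenset(MUSCLES) | {FASCIA, FEMUR}

# tissue class codes used in every label map (generator ground truth and
# pipeline output alike)
BACKGROUND = 0
MUSCLE = 1
INTRAMAT = 2
INTERMAT = 3
SAT = 4
FEMUR_CLASS = 5
UNASSIGNED = 6

CLASS_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    MUSCLE: "muscle",
    INTRAMAT: "IntraMAT",
    INTERMAT: "InterMAT",
    SAT: "SAT",
    FEMUR_CLASS: "femur",
    UNASSIGNED: "unassigned",
}


def muscle_group_of(muscle: str) -> str:
    for group, members in MUSCLE_GROUPS.items():
        if muscle in members:
            return group
    raise KeyError(muscle)
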