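"""Shared image-morphology helpers."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InputError


def body_mask(slice_: np.ndarray, threshold: float) -> np.ndarray:
    """Solid mask of the imaged limb: largest supra-threshold component.

    Isolated noise speckle is suppressed by a binary opening before the
    component search and interior holes are filled, so air pixels whose
    noise exceeds the threshold do not join the mask.
    """
    supra = np.asarray(slice_) >= threshold
    opened = ndimage.binary_opening(supra)
    if not opened.any():
        opened = supra
    labels, n = ndimage.label(opened)
    if n == 0:
        raise InputError("no supra-threshold pixels; cannot find the limb")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return ndimage.binary_fill_holes(labels == (1 + int(np.argmax(sizes))))
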