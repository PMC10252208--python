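"""Small shared helpers."""

from __future__ import annotations

import numpy as np
from skimage.measure import label


def remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop connected components smaller than ``min_px`` pixels."""
    if min_px <= 1 or not mask.any():
        return mask
    lab = label(mask)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    return keep[lab]
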