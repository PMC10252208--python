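"""Immunofluorescence quantification.

Nucleus-anchored marker counting (percentage of marker-positive cells among
Hoechst-positive nuclei), apoptotic fraction within the neuronal (MAP2)
population, background-corrected intensity per unit neurite length, and the
acetylated/alpha-tubulin intensity ratio.

Background correction uses a blank area between neurites, selected
automatically as the tile of a regular grid with the lowest mean intensity;
positivity thresholds default to blank mean + 3 blank SDs, applied equally
across all conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, skeletonize

from ._util import remove_small

from .core import Calibration, ImageStack

__all__ = [
    "IFQuantification",
    "blank_region_stats",
    "segment_nuclei",
    "count_marker_positive",
    "cc3_fraction_in_neurons",
    "intensity_per_neurite_length",
    "acetylation_ratio",
    "quantify_if_image",
]


@dataclass
class IFQuantification:
    """Per-image IF readouts (percentages in %, intensities in a.u./µm)."""

    percent_positive: dict[str, float]
    percent_smi32_in_map2: float = np.nan
    percent_cc3_in_map2: float = np.nan
    map2_intensity_per_length: float = np.nan
    smi32_intensity_per_length: float = np.nan
    acetylated_over_alpha_tubulin: float = np.nan

    def __post_init__(self) -> None:
        for name, v in self.percent_positive.items():
            if np.isfinite(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"percentage out of range for {name}: {v}")


def blank_region_stats(channel: np.ndarray, tile_px: int = 32) -> tuple[float, float]:
    """Mean and SD of the lowest-mean tile of a regular grid (the blank area)."""
    img = np.asarray(channel, dtype=float)
    h, w = img.shape
    best = None
    for r0 in range(0, h - tile_px + 1, tile_px):
        for c0 in range(0, w - tile_px + 1, tile_px):
            tile = img[r0 : r0 + tile_px, c0 : c0 + tile_px]
            m = float(tile.mean())
            if best is None or m < best[0]:
                best = (m, float(tile.std()))
    if best is None:  # image smaller than one tile
        return float(img.mean()), float(img.std())
    return best


def segment_nuclei(
    nuclei_channel: np.ndarray,
    min_area_px: int = 15,
    threshold: float | None = None,
) -> np.ndarray:
    """Label image of nuclei: threshold (Otsu default) + size filter."""
    img = np.asarray(nuclei_channel, dtype=float)
    if threshold is None:
        threshold = threshold_otsu(img)
    mask = remove_small(img > threshold, min_area_px)
    return label(mask)


def _positive_cells(
    marker: np.ndarray,
    nuclei_labels: np.ndarray,
    threshold: float | None,
    dilation_px: int,
    threshold_sds: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-nucleus marker means and positivity flags."""
    if threshold is None:
        mean_b, sd_b = blank_region_stats(marker)
        threshold = mean_b + threshold_sds * sd_b
    dil = _dilated_labels(nuclei_labels, dilation_px)
    ids = np.unique(nuclei_labels)
    ids = ids[ids > 0]
    means = ndi.mean(marker, labels=dil, index=ids)
    return means, means > threshold


def _dilated_labels(labels: np.ndarray, dilation_px: int) -> np.ndarray:
    """Dilate every labeled region at once (nuclei are well separated)."""
    if dilation_px <= 0:
        return labels
    return ndi.grey_dilation(labels, footprint=disk(dilation_px))


def count_marker_positive(
    image: ImageStack,
    marker: str,
    nuclei_channel: str = "hoechst",
    threshold: float | None = None,
    dilation_px: int = 3,
    threshold_sds: float = 3.0,
    min_nucleus_area_px: int = 15,
) -> tuple[float, pd.DataFrame]:
    """Percentage of marker-positive cells among all nuclei.

    Nuclei are segmented on the Hoechst channel; a cell is marker-positive
    when the mean marker intensity over its dilated nuclear region exceeds
    the threshold (default: blank-area mean + ``threshold_sds`` blank SDs).
    Returns (percentage, per-cell table). Raises ``ValueError`` with zero
    nuclei.
    """
    nuc = image.channel(nuclei_channel)[0]
    mk = image.channel(marker)[0]
    labels = segment_nuclei(nuc, min_area_px=min_nucleus_area_px)
    n = labels.max()
    if n == 0:
        raise ValueError("no nuclei segmented")
    means, pos = _positive_cells(mk, labels, threshold, dilation_px, threshold_sds)
    cells = pd.DataFrame({"cell": np.arange(1, n + 1), "marker_mean": means, "positive": pos})
    return 100.0 * pos.sum() / n, cells


def cc3_fraction_in_neurons(
    image: ImageStack,
    cc3_channel: str = "CC3",
    map2_channel: str = "MAP2",
    nuclei_channel: str = "hoechst",
    threshold_sds: float = 3.0,
    dilation_px: int = 3,
) -> float:
    """Percent CC3-positive cells among MAP2-mask-positive cells.

    A binary MAP2 mask (blank + 3 SD threshold) restricts the analysis to
    neurons: a cell counts as neuronal when its dilated nuclear region
    overlaps the MAP2 mask. Raises ``ValueError`` when the MAP2 mask or the
    neuronal population is empty.
    """
    nuc = image.channel(nuclei_channel)[0]
    map2 = image.channel(map2_channel)[0]
    cc3 = image.channel(cc3_channel)[0]
    labels = segment_nuclei(nuc)
    if labels.max() == 0:
        raise ValueError("no nuclei segmented")
    mean_b, sd_b = blank_region_stats(map2)
    map2_mask = remove_small(map2 > (mean_b + threshold_sds * sd_b), 8)
    if not map2_mask.any():
        raise ValueError("empty MAP2 mask")
    _, cc3_pos = _positive_cells(cc3, labels, None, dilation_px, threshold_sds)
    dil = _dilated_labels(labels, dilation_px)
    overlap = ndi.maximum(map2_mask.astype(float), labels=dil, index=np.arange(1, labels.max() + 1))
    neuronal = np.asarray(overlap) > 0
    if not neuronal.any():
        raise ValueError("no MAP2-positive cells")
    return 100.0 * (cc3_pos & neuronal).sum() / neuronal.sum()


def intensity_per_neurite_length(
    image: ImageStack,
    marker: str,
    calib: Calibration | None = None,
    threshold_sds: float = 3.0,
    tile_px: int = 32,
) -> float:
    """Background-corrected integrated intensity per µm of neurite skeleton.

    Background is the blank-tile mean; the neurite mask thresholds the
    corrected channel at ``threshold_sds`` blank SDs; total length is the
    skeleton pixel count converted to µm. Raises ``ValueError`` when no
    neurite mask survives.
    """
    calib = calib or image.calibration
    ch = image.channel(marker)[0].astype(float)
    mean_b, sd_b = blank_region_stats(ch, tile_px)
    corrected = np.clip(ch - mean_b, 0.0, None)
    mask = corrected > threshold_sds * sd_b
    mask = remove_small(mask, 10)
    if not mask.any():
        raise ValueError("no neurite mask above background")
    skel = skeletonize(mask)
    length_um = float(skel.sum()) * calib.pixel_size_um
    if length_um == 0:
        raise ValueError("degenerate skeleton")
    return float(corrected[mask].sum()) / length_um


def acetylation_ratio(
    image: ImageStack,
    acetyl_channel: str = "AcTub",
    alpha_channel: str = "aTub",
    threshold_sds: float = 3.0,
) -> float:
    """Ratio of background-corrected mean intensities over the shared neurite mask.

    Both tubulin channels are corrected with their own blank areas; the mask
    comes from the alpha-tubulin (structural) channel. Raises ``ValueError``
    on zero alpha-tubulin signal.
    """
    ac = image.channel(acetyl_channel)[0].astype(float)
    al = image.channel(alpha_channel)[0].astype(float)
    mean_ac, _ = blank_region_stats(ac)
    mean_al, sd_al = blank_region_stats(al)
    al_corr = np.clip(al - mean_al, 0.0, None)
    ac_corr = np.clip(ac - mean_ac, 0.0, None)
    mask = remove_small(al_corr > threshold_sds * sd_al, 10)
    if not mask.any() or al_corr[mask].mean() == 0:
        raise ValueError("no alpha-tubulin signal")
    return float(ac_corr[mask].mean() / al_corr[mask].mean())


def quantify_if_image(
    image: ImageStack,
    markers: tuple[str, ...] | None = None,
    conditional: dict[str, str] | None = None,
    **kwargs,
) -> IFQuantification:
    """Convenience per-image quantification of all requested marker percentages.

    ``conditional`` maps child -> parent for within-population percentages
    (e.g. ``{"SMI32": "MAP2"}`` gives percent SMI32+ within the MAP2+
    population, reported as ``percent_smi32_in_map2``).
    """
    markers = markers or tuple(n for n in image.channel_names if n != "hoechst")
    conditional = conditional or {}
    pct: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}
    for m in markers:
        pct[m], tables[m] = count_marker_positive(image, m, **kwargs)
    smi32_in_map2 = np.nan
    if "SMI32" in conditional and conditional["SMI32"] == "MAP2" and {"SMI32", "MAP2"} <= set(tables):
        parent = tables["MAP2"]["positive"].to_numpy()
        child = tables["SMI32"]["positive"].to_numpy()
        if parent.sum() > 0:
            smi32_in_map2 = 100.0 * (child & parent).sum() / parent.sum()
    return IFQuantification(percent_positive=pct, percent_smi32_in_map2=smi32_in_map2)
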