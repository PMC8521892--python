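"""Per-ROI segmentation: vein exclusion, fibrosis, and sinusoidal-lumen masks.

A region of interest (ROI) is a fixed-size RGB tile centered on a
centrilobular vein of a Masson's-trichrome-stained liver section.  The
pipeline for one ROI is:

1. attach the physical pixel scale (default 4.55 um/pixel);
2. fill the (manually delineated) centrilobular vein with pure white so it
   falls outside every segmentation band;
3. threshold the blue collagen signal for fibrosis, after a 3x3 mean smooth;
4. threshold black-filled lumen annotations for the sinusoidal lumen, or run
   the automated near-white candidate detector.

The vein mask is a required input when a vein is present in the field: vein
delineation is deliberately manual (an editorial judgement about vessel-wall
boundaries), so this package consumes the mask rather than guessing it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skimage.measure import label
from skimage.morphology import remove_small_objects

from .colorspace import (
    FIBROSIS_BAND,
    LUMEN_BAND,
    HSBBand,
    rgb_to_hsb,
    smooth,
    threshold_hsb,
)

__all__ = [
    "ROIImage",
    "DEFAULT_SCALE_UM_PER_PX",
    "exclude_vein",
    "segment_fibrosis",
    "segment_lumen_annotated",
    "detect_lumen_candidates",
]

DEFAULT_SCALE_UM_PER_PX = 4.55


@dataclass
class ROIImage:
    """One centrilobular ROI: pixels, physical scale, optional vein mask.

    ``lumen_annotation=True`` declares that sinusoidal lumens have been
    pre-filled with black pixels by upstream manual annotation, enabling
    :func:`segment_lumen_annotated`.
    """

    pixels: np.ndarray
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    vein_mask: Optional[np.ndarray] = None
    lumen_annotation: bool = False
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"ROI pixels must be (H, W, 3) RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError("ROI pixels must be 8-bit (uint8)")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        if self.vein_mask is not None:
            self.vein_mask = np.asarray(self.vein_mask).astype(bool)
            if self.vein_mask.shape != self.pixels.shape[:2]:
                raise ValueError(
                    "vein mask shape "
                    f"{self.vein_mask.shape} does not match image {self.pixels.shape[:2]}"
                )

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]


def exclude_vein(roi: ROIImage, vein: np.ndarray) -> ROIImage:
    """Fill the vein region with pure white and attach the mask to the ROI.

    White pixels (brightness 255) lie above both the fibrosis brightness
    bound (248) and the lumen bound (50), so the filled vein can never enter
    a component mask; the mask is additionally subtracted downstream.
    """
    vein = np.asarray(vein).astype(bool)
    if vein.shape != roi.pixels.shape[:2]:
        raise ValueError(
            f"vein mask shape {vein.shape} does not match image {roi.pixels.shape[:2]}"
        )
    pixels = roi.pixels.copy()
    pixels[vein] = 255
    return replace(roi, pixels=pixels, vein_mask=vein)


def _subtract_vein(mask: np.ndarray, roi: ROIImage) -> np.ndarray:
    if roi.vein_mask is not None:
        mask = mask & ~roi.vein_mask
    return mask


def segment_fibrosis(
    roi: ROIImage,
    band: HSBBand = FIBROSIS_BAND,
    smoothing: bool = True,
) -> np.ndarray:
    """Segment blue-stained collagen (centrilobular/perisinusoidal fibrosis).

    Applies a 3x3 mean smooth (unless disabled), converts to HSB, and
    thresholds with the collagen band (hue 140-190, sat 0-255, bri 0-248).
    Vein pixels are removed from the result.
    """
    pixels = smooth(roi.pixels) if smoothing else roi.pixels
    mask = threshold_hsb(rgb_to_hsb(pixels), band)
    return _subtract_vein(mask, roi)


def segment_lumen_annotated(roi: ROIImage, band: HSBBand = LUMEN_BAND) -> np.ndarray:
    """Segment black-filled sinusoidal lumen annotations.

    The ROI must carry ``lumen_annotation=True`` — i.e. lumens were manually
    traced and filled with black upstream.  No smoothing is applied: the
    fills are flat by construction and blurring would erode thin channels.
    """
    if not roi.lumen_annotation:
        raise ValueError(
            "ROI is not lumen-annotated: segment_lumen_annotated requires lumens "
            "pre-filled with black pixels (set lumen_annotation=True), or use "
            "detect_lumen_candidates for the automated route"
        )
    mask = threshold_hsb(rgb_to_hsb(roi.pixels), band)
    return _subtract_vein(mask, roi)


def detect_lumen_candidates(
    roi: ROIImage,
    bri_min: int = 230,
    sat_max: int = 40,
    min_area_px: int = 4,
) -> np.ndarray:
    """Automated *candidate* detector for sinusoidal lumens.

    Selects near-white unstained space (brightness >= ``bri_min`` and
    saturation <= ``sat_max``), removes the vein, and drops 8-connected
    components smaller than ``min_area_px``.

    This is candidate quality only: near-white space also includes fat
    droplets (microvesicular steatosis), ballooned hepatocytes and tears,
    which this detector cannot distinguish from lumens.  The annotated route
    (:func:`segment_lumen_annotated`) is the reference procedure.
    """
    if not (0 <= bri_min <= 255 and 0 <= sat_max <= 255):
        raise ValueError("bri_min and sat_max must be in [0, 255]")
    if min_area_px < 0:
        raise ValueError("min_area_px must be >= 0")
    hsb = rgb_to_hsb(roi.pixels)
    mask = (hsb[..., 2] >= bri_min) & (hsb[..., 1] <= sat_max)
    mask = _subtract_vein(mask, roi)
    if min_area_px > 1:
        # drop 8-connected components with fewer than min_area_px pixels
        mask = remove_small_objects(mask, max_size=min_area_px - 1, connectivity=2)
    return mask
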