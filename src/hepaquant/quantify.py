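"""Physical-area measurement and the CFR / SLR ratio statistics.

CFR (centrilobular fibrosis ratio) and SLR (sinusoidal lumen ratio) are the
percentages of tissue area occupied by the fibrosis and lumen masks:

    CFR% = 100 * fibrosis_area / (total_area - vein_area)
    SLR% = 100 * lumen_area    / (total_area - vein_area)

The denominator is the ROI area minus the excluded centrilobular vein — the
"tissue area" — since the vein lumen is not tissue and was deliberately
removed before segmentation.  ``include_vein_in_denominator`` restores the
full ROI area for sensitivity analysis.

Areas are in um^2: pixel count times the square of the pixel scale.  Ratios
are kept at full floating precision; rounding happens only in the CSV layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ROIMeasurement",
    "SlideSummary",
    "measure_area",
    "compute_ratios",
    "measure_roi",
    "aggregate_slide",
]


@dataclass(frozen=True)
class ROIMeasurement:
    """Areas (um^2) and ratio statistics (%) for one ROI."""

    roi_id: str
    total_area_um2: float
    vein_area_um2: float
    tissue_area_um2: float
    fibrosis_area_um2: float
    lumen_area_um2: float
    cfr_percent: float
    slr_percent: float


@dataclass(frozen=True)
class SlideSummary:
    """Per-slide arithmetic means of ROI-level ratios."""

    slide_id: str
    n_rois: int
    mean_cfr_percent: float
    mean_slr_percent: float


def measure_area(mask: np.ndarray, scale_um_per_px: float) -> float:
    """Physical area of a boolean mask: true-pixel count x scale^2 (um^2)."""
    if not scale_um_per_px > 0:
        raise ValueError("scale_um_per_px must be positive")
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    return float(np.count_nonzero(mask)) * scale_um_per_px**2


def compute_ratios(
    fibrosis_area: float,
    lumen_area: float,
    total_area: float,
    vein_area: float = 0.0,
    include_vein_in_denominator: bool = False,
) -> tuple:
    """(CFR%, SLR%) from component areas; see module docstring for formulas.

    Raises ``ZeroDivisionError`` when the denominator (tissue area, or total
    area if the vein is included) is zero — an undefined ratio is an error,
    never a silent 0.
    """
    if vein_area > total_area:
        raise ValueError("vein_area exceeds total_area")
    tissue = total_area if include_vein_in_denominator else total_area - vein_area
    for name, a in (("fibrosis_area", fibrosis_area), ("lumen_area", lumen_area)):
        if a < 0:
            raise ValueError(f"{name} is negative")
        if a > tissue + 1e-9:
            raise ValueError(f"{name} ({a}) exceeds the denominator area ({tissue})")
    if tissue == 0:
        raise ZeroDivisionError(
            "tissue area is zero (vein fills the ROI): CFR/SLR undefined"
        )
    return 100.0 * fibrosis_area / tissue, 100.0 * lumen_area / tissue


def measure_roi(
    roi_id: str,
    fibrosis_mask: np.ndarray,
    lumen_mask: np.ndarray,
    scale_um_per_px: float,
    vein_mask: np.ndarray | None = None,
    shape: tuple | None = None,
    include_vein_in_denominator: bool = False,
) -> ROIMeasurement:
    """Assemble a full :class:`ROIMeasurement` from component masks."""
    shape = fibrosis_mask.shape if shape is None else shape
    total = float(np.prod(shape)) * scale_um_per_px**2
    vein = (
        measure_area(vein_mask, scale_um_per_px) if vein_mask is not None else 0.0
    )
    fib = measure_area(fibrosis_mask, scale_um_per_px)
    lum = measure_area(lumen_mask, scale_um_per_px)
    cfr, slr = compute_ratios(
        fib, lum, total, vein, include_vein_in_denominator=include_vein_in_denominator
    )
    return ROIMeasurement(
        roi_id=roi_id,
        total_area_um2=total,
        vein_area_um2=vein,
        tissue_area_um2=total - vein,
        fibrosis_area_um2=fib,
        lumen_area_um2=lum,
        cfr_percent=cfr,
        slr_percent=slr,
    )


def aggregate_slide(
    measurements: Sequence[ROIMeasurement], slide_id: str | None = None
) -> SlideSummary:
    """Arithmetic mean of CFR and SLR over the ROIs of one slide.

    When ``slide_id`` is omitted it is derived from the ROI ids, which must
    then all share the same ``slide_roiN`` prefix.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("cannot aggregate an empty list of measurements")
    if slide_id is None:
        prefixes = {m.roi_id.rsplit("_", 1)[0] for m in measurements}
        if len(prefixes) != 1:
            raise ValueError(
                f"measurements span multiple slides: {sorted(prefixes)}"
            )
        slide_id = prefixes.pop()
    return SlideSummary(
        slide_id=slide_id,
        n_rois=len(measurements),
        mean_cfr_percent=float(np.mean([m.cfr_percent for m in measurements])),
        mean_slr_percent=float(np.mean([m.slr_percent for m in measurements])),
    )
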