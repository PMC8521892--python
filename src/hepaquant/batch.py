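"""File I/O, configuration, and the batch engine.

The batch engine reproduces a macro-style run: every ROI image in a folder
is processed with one fixed configuration, one result row is written per
image, and per-slide summaries are computed by grouping filenames on the
``slideID_roiN`` convention.  Processing order is lexicographic by filename
and the engine is stateless across images, so a rerun on the same inputs
produces a byte-identical CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .colorspace import FIBROSIS_BAND, LUMEN_BAND, HSBBand
from .quantify import ROIMeasurement, aggregate_slide, measure_roi
from .segmentation import (
    DEFAULT_SCALE_UM_PER_PX,
    ROIImage,
    detect_lumen_candidates,
    exclude_vein,
    segment_fibrosis,
    segment_lumen_annotated,
)

__all__ = [
    "BatchConfig",
    "load_roi",
    "read_mask",
    "write_mask",
    "process_roi",
    "run_batch",
    "load_config",
]

logger = logging.getLogger("hepaquant")

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff")
_MASK_SUFFIXES = ("_vein", "_fibrosis", "_lumen")

#: Result CSV column order; areas in um^2, ratios in percent of tissue area.
RESULT_COLUMNS = [
    "roi_id",
    "slide_id",
    "total_area_um2",
    "vein_area_um2",
    "tissue_area_um2",
    "fibrosis_area_um2",
    "lumen_area_um2",
    "cfr_percent",
    "slr_percent",
    "status",
]


@dataclass(frozen=True)
class BatchConfig:
    """One macro-equivalent run configuration."""

    input_dir: Path
    output_csv: Path
    mask_dir: Optional[Path] = None
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    fibrosis_band: HSBBand = FIBROSIS_BAND
    lumen_band: HSBBand = LUMEN_BAND
    smoothing: bool = True
    lumen_mode: str = "annotated"  # "annotated" | "automated"
    random_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_dir", Path(self.input_dir))
        object.__setattr__(self, "output_csv", Path(self.output_csv))
        if self.mask_dir is not None:
            object.__setattr__(self, "mask_dir", Path(self.mask_dir))
        if self.lumen_mode not in ("annotated", "automated"):
            raise ValueError("lumen_mode must be 'annotated' or 'automated'")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def load_roi(
    path,
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX,
    vein_mask_path=None,
    lumen_annotation: bool = False,
) -> ROIImage:
    """Load an 8-bit RGB TIFF/PNG as an :class:`ROIImage`.

    16-bit or grayscale rasters are rejected with a clear message; an
    attached vein mask must match the image dimensions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_image(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # tolerate an opaque alpha channel
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path.name}: expected 3-channel RGB, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path.name}: expected 8-bit RGB, got dtype {arr.dtype} "
            "(convert 16-bit scans to 8-bit before analysis)"
        )
    roi = ROIImage(
        pixels=arr,
        scale_um_per_px=scale_um_per_px,
        lumen_annotation=lumen_annotation,
        roi_id=path.stem,
    )
    if vein_mask_path is not None:
        roi = exclude_vein(roi, read_mask(vein_mask_path))
    return roi


def read_mask(path) -> np.ndarray:
    """Read a single-channel 8-bit mask (0 background, nonzero component)."""
    path = Path(path)
    arr = _read_image(path)
    if arr.ndim == 3:
        if arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"{path.name}: unsupported mask shape {arr.shape}")
        if arr.shape[2] >= 3 and not (
            (arr[..., 0] == arr[..., 1]).all() and (arr[..., 0] == arr[..., 2]).all()
        ):
            raise ValueError(f"{path.name}: mask must be single-channel")
        arr = arr[..., 0]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path.name}: mask must be 8-bit, got {arr.dtype}")
    return arr > 0


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a boolean mask as 8-bit PNG/TIFF (0/255); bit-exact round-trip."""
    import imageio.v3 as iio

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)
    return path


def slide_id_of(roi_id: str) -> str:
    """Slide grouping key under the ``slideID_roiN`` filename convention."""
    stem, _, tail = roi_id.rpartition("_")
    if stem and tail.startswith("roi"):
        return stem
    return roi_id


def process_roi(roi: ROIImage, config: BatchConfig) -> tuple:
    """Run the full single-ROI pipeline; returns (measurement, masks dict)."""
    fibrosis = segment_fibrosis(roi, band=config.fibrosis_band,
                                smoothing=config.smoothing)
    if config.lumen_mode == "annotated":
        lumen = segment_lumen_annotated(roi, band=config.lumen_band)
    else:
        lumen = detect_lumen_candidates(roi)
        lumen = lumen & ~fibrosis  # keep component masks disjoint
    m = measure_roi(
        roi_id=roi.roi_id,
        fibrosis_mask=fibrosis,
        lumen_mask=lumen,
        scale_um_per_px=roi.scale_um_per_px,
        vein_mask=roi.vein_mask,
        shape=roi.shape,
    )
    return m, {"fibrosis": fibrosis, "lumen": lumen, "vein": roi.vein_mask}


def _find_images(input_dir: Path) -> list[Path]:
    files = [
        p
        for p in sorted(input_dir.iterdir())
        if p.suffix.lower() in IMAGE_EXTENSIONS
        and not any(p.stem.endswith(s) for s in _MASK_SUFFIXES)
    ]
    return files


def run_batch(config: BatchConfig) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Process every image in ``config.input_dir``; write result CSVs.

    Returns ``(results, slide_summaries, n_failures)``.  Exactly one row is
    emitted per input image; images that fail to process are flagged in the
    ``status`` column (and excluded from slide means) rather than silently
    skipped.  The slide summary CSV is written next to the results CSV with
    a ``_slides`` suffix, and a run log records configuration and per-image
    status.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    input_dir = config.input_dir
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {input_dir}")
    images = _find_images(input_dir)
    if not images:
        raise ValueError(f"no TIFF/PNG images found in {input_dir}")

    log_lines = [
        f"hepaquant {__version__} batch run",
        f"config: {config}",
        f"images: {len(images)}",
    ]
    rows = []
    measurements: dict[str, list[ROIMeasurement]] = {}
    n_fail = 0
    for path in images:
        roi_id = path.stem
        try:
            vein_path = None
            if config.mask_dir is not None:
                candidate = Path(config.mask_dir) / f"{roi_id}_vein.png"
                if candidate.exists():
                    vein_path = candidate
            roi = load_roi(
                path,
                scale_um_per_px=config.scale_um_per_px,
                vein_mask_path=vein_path,
                lumen_annotation=config.lumen_mode == "annotated",
            )
            m, _ = process_roi(roi, config)
            row = {
                "roi_id": m.roi_id,
                "slide_id": slide_id_of(m.roi_id),
                "total_area_um2": m.total_area_um2,
                "vein_area_um2": m.vein_area_um2,
                "tissue_area_um2": m.tissue_area_um2,
                "fibrosis_area_um2": m.fibrosis_area_um2,
                "lumen_area_um2": m.lumen_area_um2,
                "cfr_percent": m.cfr_percent,
                "slr_percent": m.slr_percent,
                "status": "ok",
            }
            measurements.setdefault(row["slide_id"], []).append(m)
            log_lines.append(f"{roi_id}: ok")
        except Exception as exc:  # per-image failure must not kill the batch
            n_fail += 1
            row = {
                "roi_id": roi_id,
                "slide_id": slide_id_of(roi_id),
                **{c: float("nan") for c in RESULT_COLUMNS[2:-1]},
                "status": f"error: {exc}",
            }
            log_lines.append(f"{roi_id}: FAILED ({exc})")
            logger.warning("failed to process %s: %s", roi_id, exc)
        rows.append(row)

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    summaries = pd.DataFrame(
        [
            {
                "slide_id": s.slide_id,
                "n_rois": s.n_rois,
                "mean_cfr_percent": s.mean_cfr_percent,
                "mean_slr_percent": s.mean_slr_percent,
            }
            for s in (
                aggregate_slide(ms, slide_id=sid)
                for sid, ms in sorted(measurements.items())
            )
        ],
        columns=["slide_id", "n_rois", "mean_cfr_percent", "mean_slr_percent"],
    )

    out = config.output_csv
    out.parent.mkdir(parents=True, exist_ok=True)
    header = (
        "# hepaquant batch results: one row per ROI image; areas in um^2 "
        "(pixel count x scale^2); cfr_percent/slr_percent in % of tissue "
        "(ROI minus vein) area\n"
    )
    with open(out, "w") as fh:
        fh.write(header)
        results.round(2).to_csv(fh, index=False)
    slides_csv = out.with_name(out.stem + "_slides" + out.suffix)
    with open(slides_csv, "w") as fh:
        fh.write("# hepaquant slide summaries: arithmetic means over the ROIs "
                 "of each slide\n")
        summaries.round(2).to_csv(fh, index=False)
    log_lines.append(f"failures: {n_fail}")
    out.with_suffix(".log").write_text("\n".join(log_lines) + "\n")
    return results, summaries, n_fail


def _parse_band(text: str) -> HSBBand:
    parts = [int(x) for x in text.replace(",", " ").split()]
    if len(parts) != 6:
        raise ValueError(f"band needs 6 integers (hue lo/hi, sat lo/hi, bri lo/hi): {text!r}")
    lo, hi = parts[0], parts[1]
    return HSBBand(*parts, hue_wrap=lo > hi)


def load_config(path, **overrides) -> BatchConfig:
    """Load a flat ``key = value`` config file; keyword overrides win."""
    values: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        val = val.strip()
        if key in ("fibrosis_band", "lumen_band"):
            values[key] = _parse_band(val)
        elif key == "scale_um_per_px":
            values[key] = float(val)
        elif key == "smoothing":
            values[key] = val.lower() in ("1", "true", "yes", "on")
        elif key == "random_seed":
            values[key] = int(val)
        elif key in ("input_dir", "mask_dir", "output_csv"):
            values[key] = Path(val)
        elif key in ("lumen_mode", "log_level"):
            values[key] = val
        else:
            raise ValueError(f"unknown config key: {key}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    return BatchConfig(**values)
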