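"""Synthetic Masson's-trichrome histology phantoms with ground-truth masks.

A phantom emulates the morphology of a centrilobular ROI: a central vein
(near-white vessel lumen), thin sinusoid channels radiating outward
(near-white), a pericentral collagen ring (blue) optionally extended by
1-px perisinusoidal sleeves, and red/pink parenchyma elsewhere.  Optional
white fat droplets reproduce the classic confounder of automated lumen
detection.  Component placement is exact-count: the number of painted pixels
is ``round(fraction * tissue_pixels)``, so ground-truth fractions are exact
to within half a pixel's worth.

Paint colors sit well inside (collagen) or well outside (parenchyma) the
fibrosis hue band so that phantom tests isolate pipeline correctness from
stain-spectrum realism; Gaussian RGB noise probes robustness.

The cohort generator emulates a congestive-hepatopathy study design:
animals receive an ordinal CHFS grade (0-4), per-ROI fibrosis fractions are
drawn from the grade's normal distribution truncated to [0, 0.9), and a
batch-compatible folder of phantom ROIs plus a ground-truth table is
produced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from scipy.stats import truncnorm

from .colorspace import hsb_to_rgb
from .segmentation import DEFAULT_SCALE_UM_PER_PX

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
    "write_phantom",
    "write_cohort",
]

# Default CHFS grade distribution and per-grade CFR%: frequencies and group
# summaries of the emulated congestive-hepatopathy cohort design
# (50 animals, 5 ROIs each; grades 0/1/2 at 46/32/22%).
DEFAULT_CHFS_PROBS = (0.46, 0.32, 0.22)
DEFAULT_CFR_MEANS = (1.32, 8.00, 14.55)
DEFAULT_CFR_SDS = (1.07, 4.45, 6.62)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic MT ROI with known component fractions."""

    side_px: int = 341
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    vein_radius_px: int = 20
    fibrosis_fraction: float = 0.10
    lumen_fraction: float = 0.08
    perisinusoidal: bool = False
    fat_droplet_count: int = 0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_px < 8:
            raise ValueError("side_px must be >= 8")
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")
        if not 0 <= self.vein_radius_px < self.side_px / 2:
            raise ValueError("vein disk must fit inside the image")
        for name in ("fibrosis_fraction", "lumen_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.fibrosis_fraction + self.lumen_fraction >= 1:
            raise ValueError("fibrosis_fraction + lumen_fraction must be < 1")
        if self.fat_droplet_count < 0:
            raise ValueError("fat_droplet_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class Phantom:
    """A rendered phantom: RGB image plus exact ground-truth masks."""

    image: np.ndarray
    truth_fibrosis: np.ndarray
    truth_lumen: np.ndarray
    truth_vein: np.ndarray
    spec: PhantomSpec

    @property
    def tissue_px(self) -> int:
        return self.image.shape[0] * self.image.shape[1] - int(
            np.count_nonzero(self.truth_vein)
        )

    @property
    def true_cfr_percent(self) -> float:
        return 100.0 * np.count_nonzero(self.truth_fibrosis) / self.tissue_px

    @property
    def true_slr_percent(self) -> float:
        return 100.0 * np.count_nonzero(self.truth_lumen) / self.tissue_px


def _paint(rng: np.random.Generator, mask: np.ndarray, img_hsb: np.ndarray,
           hue: tuple, sat: tuple, bri: tuple, hue_wrap: bool = False) -> None:
    """Paint masked pixels with HSB values drawn uniformly from the ranges."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        return
    if hue_wrap:
        # interval straddling 255 -> 0, e.g. (245, 10) for red/pink
        span = (255 - hue[0] + 1) + (hue[1] + 1)
        h = (hue[0] + rng.integers(0, span, n)) % 256
    else:
        h = rng.integers(hue[0], hue[1] + 1, n)
    img_hsb[mask, 0] = h
    img_hsb[mask, 1] = rng.integers(sat[0], sat[1] + 1, n)
    img_hsb[mask, 2] = rng.integers(bri[0], bri[1] + 1, n)


def _radial_channels(
    yy: np.ndarray,
    xx: np.ndarray,
    r: np.ndarray,
    r_start: float,
    n_pixels: int,
    rng: np.random.Generator,
    forbidden: np.ndarray,
) -> np.ndarray:
    """Exact-count mask of thin channels radiating from ``r_start`` outward.

    Spokes of half-width ~1 px are added (at jittered golden-angle spacing)
    until enough candidate pixels exist; candidates are then consumed in
    order of increasing radius so all channels grow outward together.
    """
    shape = r.shape
    if n_pixels == 0:
        return np.zeros(shape, dtype=bool)
    theta = np.arctan2(yy, xx)
    allowed = (r >= r_start) & ~forbidden
    if not allowed.any():
        raise ValueError("no room for sinusoid channels outside the fibrosis ring")

    candidates = np.zeros(shape, dtype=bool)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phase = rng.uniform(0, 2 * np.pi)
    n_spokes = 12
    max_spokes = 512
    while True:
        angles = (phase + golden * np.arange(n_spokes)) % (2 * np.pi)
        candidates[:] = False
        for phi in angles:
            d = theta - phi
            # perpendicular distance of the pixel to the ray at angle phi
            perp = np.abs(r * np.sin(d))
            along = np.cos(d) > 0
            candidates |= (perp <= 1.0) & along
        candidates &= allowed
        if int(np.count_nonzero(candidates)) >= n_pixels or n_spokes >= max_spokes:
            break
        n_spokes *= 2
    if int(np.count_nonzero(candidates)) < n_pixels:
        raise ValueError(
            "lumen_fraction infeasible for this geometry: "
            f"only {int(np.count_nonzero(candidates))} channel pixels available "
            f"for {n_pixels} requested"
        )
    idx = np.flatnonzero(candidates.ravel())
    order = np.argsort(r.ravel()[idx], kind="stable")
    keep = idx[order[:n_pixels]]
    mask = np.zeros(r.size, dtype=bool)
    mask[keep] = True
    return mask.reshape(shape)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom deterministically from its spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.side_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    yy = yy - c
    xx = xx - c
    r = np.hypot(yy, xx)

    vein = r <= spec.vein_radius_px
    tissue_px = n * n - int(np.count_nonzero(vein))
    n_fib = int(round(spec.fibrosis_fraction * tissue_px))
    n_lum = int(round(spec.lumen_fraction * tissue_px))
    if n_fib + n_lum > tissue_px:
        raise ValueError("component fractions infeasible for this geometry")

    tissue_flat = np.flatnonzero(~vein.ravel())
    r_flat = r.ravel()

    # Pericentral ring extent if the nearest n_fib tissue pixels were taken:
    # channels start a 3-px safety margin beyond it so that 3x3 smoothing
    # never mixes near-white channel paint into the collagen ring.
    if n_fib > 0:
        ring_order = tissue_flat[np.argsort(r_flat[tissue_flat], kind="stable")]
        r_ring_outer = float(r_flat[ring_order[n_fib - 1]])
    else:
        r_ring_outer = float(spec.vein_radius_px)
    r_start = r_ring_outer + 3.0

    lumen = _radial_channels(yy, xx, r, r_start, n_lum, rng, forbidden=vein)

    sleeves = np.zeros_like(vein)
    if spec.perisinusoidal and n_fib > 0:
        sleeves = binary_dilation(lumen) & ~lumen & ~vein
        # sleeves count toward the fibrosis budget; trim farthest-first if over
        n_sleeve = int(np.count_nonzero(sleeves))
        if n_sleeve > n_fib:
            sl = np.flatnonzero(sleeves.ravel())
            drop = sl[np.argsort(r_flat[sl], kind="stable")[n_fib:]]
            flat = sleeves.ravel()
            flat[drop] = False
            sleeves = flat.reshape(vein.shape)
            n_sleeve = n_fib

    n_ring = n_fib - int(np.count_nonzero(sleeves))
    ring = np.zeros_like(vein)
    if n_ring > 0:
        free = np.flatnonzero((~vein & ~lumen & ~sleeves).ravel())
        order = free[np.argsort(r_flat[free], kind="stable")]
        flat = ring.ravel()
        flat[order[:n_ring]] = True
        ring = flat.reshape(vein.shape)
    fibrosis = ring | sleeves

    # fat droplets: small near-white disks in free parenchyma (a confounder
    # for automated lumen detection; never part of the lumen truth mask)
    droplets = np.zeros_like(vein)
    free = ~vein & ~lumen & ~fibrosis
    for _ in range(spec.fat_droplet_count):
        for _attempt in range(100):
            cy = rng.integers(0, n)
            cx = rng.integers(0, n)
            rad = int(rng.integers(2, 5))
            disk = (yy + c - cy) ** 2 + (xx + c - cx) ** 2 <= rad**2
            if (disk & free & ~droplets).sum() >= disk.sum() * 0.75:
                droplets |= disk & free
                break

    hsb = np.zeros((n, n, 3), dtype=np.uint8)
    parenchyma = ~vein & ~lumen & ~fibrosis & ~droplets
    # red/pink parenchyma: hue straddles 0 (346-14 deg), clearly outside the
    # collagen band even after 3x3 blending at region borders
    _paint(rng, parenchyma, hsb, hue=(245, 10), sat=(60, 180), bri=(140, 230),
           hue_wrap=True)
    _paint(rng, fibrosis, hsb, hue=(150, 185), sat=(80, 200), bri=(120, 220))
    near_white = dict(hue=(0, 255), sat=(0, 20), bri=(240, 252))
    _paint(rng, lumen, hsb, **near_white)
    _paint(rng, vein, hsb, **near_white)
    _paint(rng, droplets, hsb, **near_white)

    img = hsb_to_rgb(hsb)
    if spec.noise_sd > 0:
        noisy = img.astype(np.float64) + rng.normal(0.0, spec.noise_sd, img.shape)
        img = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)

    return Phantom(
        image=img,
        truth_fibrosis=fibrosis,
        truth_lumen=lumen,
        truth_vein=vein,
        spec=spec,
    )


def generate_cohort(
    n_animals: int = 50,
    chfs_probs: Sequence[float] = DEFAULT_CHFS_PROBS,
    cfr_means: Sequence[float] = DEFAULT_CFR_MEANS,
    cfr_sds: Sequence[float] = DEFAULT_CFR_SDS,
    rois_per_slide: int = 5,
    seed: int = 0,
    side_px: int = 341,
    **spec_overrides,
) -> tuple[list[Phantom], pd.DataFrame]:
    """Generate a graded cohort of phantom ROIs plus a ground-truth table.

    Each animal draws a CHFS grade from ``chfs_probs``; each of its ROIs
    draws a target fibrosis fraction from Normal(mean, sd)/100 of that
    grade, truncated to [0, 0.9).  Returns the phantom list (row-major by
    animal then ROI, ids ``animal{A}_roi{N}``) and a truth table with one
    row per ROI.
    """
    chfs_probs = np.asarray(chfs_probs, dtype=float)
    if chfs_probs.ndim != 1 or (chfs_probs < 0).any() or not np.isclose(
        chfs_probs.sum(), 1.0
    ):
        raise ValueError("chfs_probs must be non-negative and sum to 1")
    if len(cfr_means) != len(chfs_probs) or len(cfr_sds) != len(chfs_probs):
        raise ValueError("cfr_means/cfr_sds must match chfs_probs in length")
    if rois_per_slide < 1:
        raise ValueError("rois_per_slide must be >= 1")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")

    rng = np.random.default_rng(seed)
    scores = rng.choice(len(chfs_probs), size=n_animals, p=chfs_probs)

    phantoms: list[Phantom] = []
    rows = []
    for a, score in enumerate(scores, start=1):
        mu = cfr_means[score] / 100.0
        sd = max(cfr_sds[score] / 100.0, 1e-12)
        lo, hi = (0.0 - mu) / sd, (0.9 - mu) / sd
        fracs = truncnorm.rvs(lo, hi, loc=mu, scale=sd,
                              size=rois_per_slide, random_state=rng)
        for k, f in enumerate(fracs, start=1):
            spec = PhantomSpec(
                side_px=side_px,
                fibrosis_fraction=float(f),
                seed=int(rng.integers(0, 2**31 - 1)),
                **spec_overrides,
            )
            ph = generate_phantom(spec)
            phantoms.append(ph)
            rows.append(
                {
                    "roi_id": f"animal{a:03d}_roi{k}",
                    "animal_id": f"animal{a:03d}",
                    "chfs": int(score),
                    "target_cfr_percent": 100.0 * float(f),
                    "true_cfr_percent": ph.true_cfr_percent,
                    "true_slr_percent": ph.true_slr_percent,
                }
            )
    return phantoms, pd.DataFrame(rows)


def write_phantom(phantom: Phantom, out_dir, stem: str) -> dict:
    """Write image PNG, three mask PNGs and a JSON spec sidecar; return paths."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"image": out_dir / f"{stem}.png"}
    iio.imwrite(paths["image"], phantom.image)
    for name, mask in (
        ("fibrosis", phantom.truth_fibrosis),
        ("lumen", phantom.truth_lumen),
        ("vein", phantom.truth_vein),
    ):
        paths[name] = out_dir / f"{stem}_{name}.png"
        iio.imwrite(paths[name], (mask.astype(np.uint8) * 255))
    paths["spec"] = out_dir / f"{stem}.json"
    paths["spec"].write_text(json.dumps(asdict(phantom.spec), indent=2))
    return paths


def write_cohort(
    phantoms: Sequence[Phantom],
    truth: pd.DataFrame,
    image_dir,
    mask_dir,
) -> Path:
    """Write a batch-ready cohort: ROI PNGs, vein-mask PNGs, manifest CSV.

    Images are named ``{roi_id}.png`` (the ``slideID_roiN`` convention the
    batch engine groups by); vein masks go to ``mask_dir/{roi_id}_vein.png``.
    Returns the manifest path (written next to the images).
    """
    import imageio.v3 as iio

    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    for ph, roi_id in zip(phantoms, truth["roi_id"]):
        iio.imwrite(image_dir / f"{roi_id}.png", ph.image)
        iio.imwrite(
            mask_dir / f"{roi_id}_vein.png", ph.truth_vein.astype(np.uint8) * 255
        )
    manifest = image_dir / "manifest.csv"
    truth.to_csv(manifest, index=False)
    return manifest
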