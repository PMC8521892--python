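"""Color-model conversion and box thresholding on the 0-255 HSB scale.

The segmentation bands used throughout this package are expressed on the
hue/saturation/brightness model with every channel on an integer 0-255 scale,
the convention of the color-threshold tool the bands were calibrated in.  Hue
is the standard hexcone angle remapped linearly from [0, 360) degrees to
[0, 255] (so pure blue, 240 deg, sits at 170).  Saturation and brightness are
the hexcone S and V scaled to 0-255.

Conversion is carried out in exact integer arithmetic with half-up rounding:
with 8-bit inputs every channel value is a small rational, and exact
arithmetic makes threshold membership at band boundaries deterministic and
platform-independent (floating-point evaluation can mis-round exact .5
cases such as 255/6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HSBBand",
    "FIBROSIS_BAND",
    "LUMEN_BAND",
    "rgb_to_hsb",
    "hsb_to_rgb",
    "threshold_hsb",
    "smooth",
]


@dataclass(frozen=True)
class HSBBand:
    """Inclusive box in hue/saturation/brightness space, each channel 0-255.

    ``hue_lo > hue_hi`` is permitted only with ``hue_wrap=True``, in which
    case the hue interval wraps around 255 -> 0 (useful for red bands).
    """

    hue_lo: int
    hue_hi: int
    sat_lo: int
    sat_hi: int
    bri_lo: int
    bri_hi: int
    hue_wrap: bool = False

    def __post_init__(self) -> None:
        for name in ("hue_lo", "hue_hi", "sat_lo", "sat_hi", "bri_lo", "bri_hi"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 255):
                raise ValueError(f"{name}={v!r} outside the integer range [0, 255]")
        if self.sat_lo > self.sat_hi:
            raise ValueError("sat_lo > sat_hi")
        if self.bri_lo > self.bri_hi:
            raise ValueError("bri_lo > bri_hi")
        if self.hue_lo > self.hue_hi and not self.hue_wrap:
            raise ValueError("hue_lo > hue_hi requires hue_wrap=True")


#: Band calibrated for blue-stained collagen on Masson's trichrome.
FIBROSIS_BAND = HSBBand(140, 190, 0, 255, 0, 248)

#: Band selecting black-filled sinusoidal lumen annotations.
LUMEN_BAND = HSBBand(0, 255, 0, 255, 0, 50)


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    if img.dtype != np.uint8:
        if not np.issubdtype(img.dtype, np.integer):
            raise ValueError("RGB image must have an integer dtype with values in [0, 255]")
        if img.min() < 0 or img.max() > 255:
            raise ValueError("RGB channel values outside [0, 255]")
        img = img.astype(np.uint8)
    return img


def _div_half_up(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Exact half-up rounding of num/den for non-negative integers, den > 0."""
    return (2 * num + den) // (2 * den)


def rgb_to_hsb(img: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) uint8 RGB image to (H, W, 3) uint8 HSB.

    Standard hexcone conversion with each output channel linearly scaled to
    0-255 and rounded half-up.  Achromatic pixels (max == min) are assigned
    hue 0 and saturation 0; brightness equals the channel maximum.
    """
    img = _check_rgb(img)
    r = img[..., 0].astype(np.int64)
    g = img[..., 1].astype(np.int64)
    b = img[..., 2].astype(np.int64)

    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = mx - mn

    out = np.zeros(img.shape, dtype=np.uint8)
    out[..., 2] = mx.astype(np.uint8)  # brightness: max/255 scaled back to 0-255

    chrom = delta > 0
    d = np.where(chrom, delta, 1)  # avoid div-by-zero on achromatic pixels

    # Hue sextant numerator on the [0, 6) hexcone: pick the branch of the
    # maximal channel, then scale by 255/6 with exact half-up rounding.
    num = np.where(
        mx == r,
        (g - b) % (6 * d),
        np.where(mx == g, (b - r) + 2 * d, (r - g) + 4 * d),
    )
    hue = _div_half_up(num * 255, 6 * d)
    out[..., 0] = np.where(chrom, hue, 0).astype(np.uint8)

    sat = _div_half_up(delta * 255, np.where(mx > 0, mx, 1))
    out[..., 1] = np.where(mx > 0, sat, 0).astype(np.uint8)
    return out


def hsb_to_rgb(hsb: np.ndarray) -> np.ndarray:
    """Inverse hexcone mapping, 0-255 HSB -> 0-255 RGB (rounded half-up).

    Used by the phantom generator to paint pixels at prescribed HSB
    coordinates; it is an ordinary float implementation and does not claim
    the exact-rounding guarantee of :func:`rgb_to_hsb`.
    """
    hsb = np.asarray(hsb)
    if hsb.ndim != 3 or hsb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) HSB array, got shape {hsb.shape}")
    h = hsb[..., 0].astype(np.float64) * 6.0 / 255.0  # sextant coordinate [0, 6)
    s = hsb[..., 1].astype(np.float64) / 255.0
    v = hsb[..., 2].astype(np.float64) / 255.0

    i = np.floor(h).astype(np.int64) % 6
    f = h - np.floor(h)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))

    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    rgb = np.stack([r, g, b], axis=-1)
    return np.floor(rgb * 255.0 + 0.5).clip(0, 255).astype(np.uint8)


def threshold_hsb(hsb: np.ndarray, band: HSBBand) -> np.ndarray:
    """Boolean mask of pixels inside ``band`` (all bounds inclusive)."""
    hsb = np.asarray(hsb)
    if hsb.ndim != 3 or hsb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) HSB array, got shape {hsb.shape}")
    h = hsb[..., 0]
    s = hsb[..., 1]
    v = hsb[..., 2]
    if band.hue_lo <= band.hue_hi:
        hue_ok = (h >= band.hue_lo) & (h <= band.hue_hi)
    else:  # wraparound interval, e.g. red straddling 255 -> 0
        hue_ok = (h >= band.hue_lo) | (h <= band.hue_hi)
    return (
        hue_ok
        & (s >= band.sat_lo)
        & (s <= band.sat_hi)
        & (v >= band.bri_lo)
        & (v <= band.bri_hi)
    )


def smooth(img: np.ndarray) -> np.ndarray:
    """3x3 unweighted mean filter per channel, rounded half-up.

    Edge pixels average over the in-image part of their neighborhood only
    (no padding values enter the mean), so a constant image is a fixed point
    everywhere including its border.
    """
    from scipy.ndimage import convolve

    img = _check_rgb(img)
    kernel = np.ones((3, 3), dtype=np.float64)
    counts = convolve(
        np.ones(img.shape[:2], dtype=np.float64), kernel, mode="constant", cval=0.0
    )
    out = np.empty_like(img)
    for c in range(3):
        sums = convolve(
            img[..., c].astype(np.float64), kernel, mode="constant", cval=0.0
        )
        out[..., c] = np.floor(sums / counts + 0.5).clip(0, 255).astype(np.uint8)
    return out
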