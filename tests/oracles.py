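"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: the HSB oracle works one
pixel at a time in exact rational arithmetic (`fractions.Fraction`) straight
from the hexcone definition, and the area oracle is a plain Python loop.
"""

from fractions import Fraction


def _half_up(x: Fraction) -> int:
    from math import floor

    return floor(x + Fraction(1, 2))


def hsb_pixel(r: int, g: int, b: int) -> tuple:
    """Hexcone HSB of one 8-bit RGB pixel on the 0-255 scale, half-up rounded."""
    mx, mn = max(r, g, b), min(r, g, b)
    d = mx - mn
    if d == 0:
        hue = 0
    else:
        if mx == r:
            sextant = Fraction(g - b, d) % 6
        elif mx == g:
            sextant = Fraction(b - r, d) + 2
        else:
            sextant = Fraction(r - g, d) + 4
        hue = _half_up(sextant * Fraction(255, 6))
    sat = 0 if mx == 0 else _half_up(Fraction(d * 255, mx))
    return hue, sat, mx


def count_area_um2(mask_rows, scale: float) -> float:
    """Area by explicit double loop over a nested-list mask."""
    n = 0
    for row in mask_rows:
        for v in row:
            if v:
                n += 1
    return n * scale * scale
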