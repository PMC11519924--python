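"""Convention-pinned color-space conversions and the G/V quantifier.

Scale conventions used throughout the package:

* 8-bit channels ``r, g, b`` in [0, 255] (floats allowed for patch means);
* hue in degrees [0, 360), reported as 0 for achromatic colors;
* saturation and value as percentages [0, 100];
* CIELAB under sRGB primaries, D65 white point, 2 degree observer.

The strongly correlated quantitative parameter (SCQP) is the ratio of the
green channel to the HSV value channel, both on the [0, 1] scale.  Its
complement ``1 - G/V`` equals the HSV saturation exactly whenever green is
the minimum channel (red-family analytes), and unlike saturation it stays
monotone with concentration down to very low analyte levels.  Because G/V is
a ratio of channels, it is invariant to multiplicative illumination changes
and to gamma encoding of such changes.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "ColorValue",
    "Scqp",
    "ScqpUndefinedError",
    "rgb_to_hsv",
    "rgb_to_lab",
    "rgb_to_gray",
    "compute_scqp",
    "scqp_signal_image",
]

# ITU-R BT.601 luma weights; the conventional "weighted average" grayscale.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class ScqpUndefinedError(ValueError):
    """G/V is undefined for a pure black pixel (V = 0)."""


@dataclass(frozen=True)
class ColorValue:
    """One pixel or patch color with lazily populated HSV / L*a*b* views.

    ``r, g, b`` are 8-bit scale values in [0, 255]; floats are accepted so
    that patch means keep sub-integer precision.
    """

    r: float
    g: float
    b: float
    h: float | None = field(default=None, compare=False)
    s: float | None = field(default=None, compare=False)
    v: float | None = field(default=None, compare=False)
    L: float | None = field(default=None, compare=False)
    a: float | None = field(default=None, compare=False)
    b_star: float | None = field(default=None, compare=False)
    achromatic: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        for name, value in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not np.isfinite(value) or not (0.0 <= value <= 255.0):
                raise ValueError(f"channel {name}={value!r} outside [0, 255]")

    @property
    def rgb_norm(self) -> tuple[float, float, float]:
        return (self.r / 255.0, self.g / 255.0, self.b / 255.0)

    def with_hsv(self) -> "ColorValue":
        return rgb_to_hsv(self)

    def with_lab(self) -> "ColorValue":
        return rgb_to_lab(self)


@dataclass(frozen=True)
class Scqp:
    """The G/V ratio (``value``) and its complement (``signal = 1 - G/V``).

    ``signal`` rises with the concentration of a green-absorbing analyte and
    equals saturation/100 exactly when green is the minimum channel.
    """

    value: float
    signal: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"G/V value {self.value!r} outside [0, 1]")


def rgb_to_hsv(c: ColorValue) -> ColorValue:
    """Populate hue (degrees), saturation and value (percent).

    Standard hexcone model: V = max(R,G,B), S = 1 - min/max.  Achromatic
    pixels get hue 0 with the ``achromatic`` flag set.  Total function: any
    8-bit color maps to a valid HSV triple.
    """
    rn, gn, bn = c.rgb_norm
    h, s, v = colorsys.rgb_to_hsv(rn, gn, bn)
    achromatic = (max(rn, gn, bn) - min(rn, gn, bn)) == 0.0
    return ColorValue(
        r=c.r, g=c.g, b=c.b,
        h=0.0 if achromatic else (h * 360.0) % 360.0,
        s=s * 100.0, v=v * 100.0,
        L=c.L, a=c.a, b_star=c.b_star,
        achromatic=achromatic,
    )


def hsv_to_rgb(h: float, s: float, v: float) -> ColorValue:
    """Inverse of :func:`rgb_to_hsv`; h in degrees, s and v in percent."""
    rn, gn, bn = colorsys.hsv_to_rgb((h % 360.0) / 360.0, s / 100.0, v / 100.0)
    return ColorValue(r=rn * 255.0, g=gn * 255.0, b=bn * 255.0)


def rgb_to_lab(c: ColorValue) -> ColorValue:
    """CIELAB coordinates under sRGB / D65 / 2 degree observer.

    One fixed convention is required for testability even though camera
    L*a*b* values vary by device; sRGB-D65 is the interchange default.
    """
    arr = np.asarray(c.rgb_norm, dtype=float).reshape(1, 1, 3)
    L, a, b_star = _skcolor.rgb2lab(arr)[0, 0]
    return ColorValue(
        r=c.r, g=c.g, b=c.b, h=c.h, s=c.s, v=c.v,
        L=float(L), a=float(a), b_star=float(b_star),
        achromatic=c.achromatic,
    )


def rgb_to_gray(c: ColorValue) -> float:
    """BT.601 weighted-average grayscale intensity in [0, 1]."""
    wr, wg, wb = GRAY_WEIGHTS
    return (wr * c.r + wg * c.g + wb * c.b) / 255.0


def compute_scqp(c: ColorValue) -> Scqp:
    """G/V on the [0, 1] scale and the quantification signal 1 - G/V.

    Raises :class:`ScqpUndefinedError` for pure black (V = 0), the only
    color where the ratio is undefined.
    """
    rn, gn, bn = c.rgb_norm
    v = max(rn, gn, bn)
    if v <= 0.0:
        raise ScqpUndefinedError("G/V undefined for black pixel (V = 0)")
    value = gn / v
    return Scqp(value=value, signal=1.0 - value)


def scqp_signal_image(image: np.ndarray) -> np.ndarray:
    """Vectorized 1 - G/V over an RGB image (float [0,1] or uint8).

    Pixels with V = 0 get signal 0 (no analyte information in pure black).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if image.dtype == np.uint8:
        img = img / 255.0
    v = img.max(axis=2)
    g = img[:, :, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(v > 0, g / np.where(v > 0, v, 1.0), 1.0)
    return 1.0 - ratio
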