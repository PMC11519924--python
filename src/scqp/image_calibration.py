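"""Image corrections for ambient interference.

Two bespoke calibrations plus a gray-world white balance:

1. **Illumination-evenness equalization** — a value-channel-only multiscale
   surround (retinex-style) correction.  The V matrix of the image is
   convolved with unit-sum Gaussian kernels at three scales
   (sigma = 20, 72, 250 px); their mean ``L`` estimates the illumination
   field, and the calibrated value matrix is

       N = clip(I + k * (L_avg - L), 0, 1),     k = 1 - mu,

   with ``mu`` in [0, 1] the calibration control: mu = 1 is the identity and
   smaller mu gives a greater degree of calibration (mu = 0 flattens the
   illumination completely).  Only V is touched; hue and saturation are
   preserved exactly so the image is not color-distorted.

2. **Shooting-distance calibration** — channels are gamma-decoded to
   linear-light values ``D = 255 * (G/255)**gamma`` (display gamma default
   2.2, admissible 2.0-2.2), multiplied by an exponential distance model
   ``C_D2 = D2 * tau**(delta_distance / 5)`` with amendment factor
   tau = 1.1 per 5 cm step, then re-encoded.  The residual against a
   reference-distance image is reported as mean |D1 - C_D2|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "EvennessParams",
    "IlluminationEstimate",
    "DistanceCalibParams",
    "gaussian_kernel",
    "multiscale_surround",
    "evenness_calibrate",
    "gamma_decode",
    "gamma_encode",
    "distance_calibrate",
    "distance_calibrate_image",
    "distance_residual",
    "white_balance_grayworld",
    "extract_value_channel",
]

DEFAULT_SIGMAS = (20.0, 72.0, 250.0)
KERNEL_TRUNCATE = 3.0  # kernel support radius in units of sigma


@dataclass(frozen=True)
class EvennessParams:
    """Controls for the V-channel evenness equalization."""

    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    mu: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigmas) or len(self.sigmas) == 0:
            raise ValueError("all Gaussian scales must be positive")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu={self.mu!r} outside [0, 1]")

    @property
    def k(self) -> float:
        """Calibration index: k = 1 - mu (smaller mu, greater calibration)."""
        return 1.0 - self.mu


@dataclass(frozen=True)
class IlluminationEstimate:
    """Intermediate matrices of the evenness algorithm (all on [0, 1])."""

    I: np.ndarray  # raw value matrix
    L: np.ndarray  # multiscale surround (mean of the per-scale convolutions)
    L_avg: float
    N: np.ndarray | None = None  # calibrated value matrix


@dataclass(frozen=True)
class DistanceCalibParams:
    """Gamma and exponential-distance model parameters.

    delta_distance is (distance of the image to correct) minus (reference
    distance), in cm; tau is the per-5-cm amendment factor.
    """

    gamma: float = 2.2
    tau: float = 1.1
    delta_distance: float = 5.0

    def __post_init__(self) -> None:
        if not (2.0 <= self.gamma <= 2.2):
            raise ValueError(f"gamma={self.gamma!r} outside [2.0, 2.2]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def gaussian_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Unit-sum 2-D Gaussian kernel, truncated at ``radius`` (default 3*sigma).

    Normalization constant C = 1 / sum(F) is applied after truncation, so the
    kernel sums to exactly 1 regardless of how much mass the cut removes.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius is None:
        radius = int(np.ceil(KERNEL_TRUNCATE * sigma))
    if radius < 1:
        raise ValueError("radius must be >= 1")
    y, x = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    F = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    return F / F.sum()


def _as_float_rgb(image: np.ndarray) -> tuple[np.ndarray, bool]:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0, True
    img = img.astype(float)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("float images must lie in [0, 1]")
    return img, False


def extract_value_channel(image: np.ndarray) -> np.ndarray:
    """HSV value matrix (max over channels) on the [0, 1] scale."""
    img, _ = _as_float_rgb(image)
    return img.max(axis=2)


def _surround(I: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with the truncated unit-sum Gaussian, reflective boundaries.

    Small kernels run through the separable spatial filter; large ones
    (radius > 48 px) switch to FFT convolution on a symmetric-padded image,
    which is numerically identical (separable normalized kernels multiply
    to the joint-normalized 2-D kernel) but far cheaper at sigma = 250.
    """
    radius = int(np.ceil(KERNEL_TRUNCATE * sigma))
    if radius <= 48:
        return ndimage.gaussian_filter(I, sigma, mode="reflect", radius=radius)
    from scipy.signal import fftconvolve

    K = gaussian_kernel(sigma, radius)
    padded = np.pad(I, radius, mode="symmetric")
    return fftconvolve(padded, K, mode="valid")


def multiscale_surround(I: np.ndarray, params: EvennessParams) -> IlluminationEstimate:
    """Mean of Gaussian surrounds of ``I`` over the configured scales.

    Reflective boundary handling avoids the edge darkening that zero padding
    would introduce.  The per-scale filters are separable evaluations of the
    truncated unit-sum kernels from :func:`gaussian_kernel`.
    """
    I = np.asarray(I, dtype=float)
    if I.ndim != 2:
        raise ValueError("expected a 2-D value matrix")
    if I.min() < 0.0 or I.max() > 1.0:
        raise ValueError("value matrix must lie in [0, 1]")
    min_support = 2 * int(np.ceil(KERNEL_TRUNCATE * min(params.sigmas))) + 1
    if min(I.shape) < min_support:
        raise ValueError(
            f"image {I.shape} smaller than the smallest kernel support "
            f"({min_support} px at sigma={min(params.sigmas)})"
        )
    surrounds = [_surround(I, sigma) for sigma in params.sigmas]
    L = np.mean(surrounds, axis=0)
    L = np.clip(L, 0.0, 1.0)  # guard float round-off at the boundaries
    return IlluminationEstimate(I=I, L=L, L_avg=float(L.mean()))


def evenness_calibrate(
    image: np.ndarray, params: EvennessParams | None = None
) -> np.ndarray:
    """Equalize the illumination field of an RGB image via its V channel.

    The calibrated value matrix is N = clip(I + k*(L_avg - L)) with
    k = 1 - mu.  Each pixel's RGB triple is rescaled by N/I, which realizes
    the V replacement while preserving hue and saturation exactly (scaling
    all channels by a positive factor changes neither the hue angle nor
    1 - min/max).  Black pixels (V = 0) become neutral gray at the new V.
    Output dtype matches the input (uint8 in, uint8 out).
    """
    if params is None:
        params = EvennessParams()
    img, was_uint8 = _as_float_rgb(image)
    I = img.max(axis=2)
    est = multiscale_surround(I, params)
    N = np.clip(I + params.k * (est.L_avg - est.L), 0.0, 1.0)
    ratio = np.where(I > 0, N / np.where(I > 0, I, 1.0), 0.0)
    out = img * ratio[:, :, None]
    out[I == 0] = N[I == 0, None]  # black pixels: gray at the calibrated V
    out = np.clip(out, 0.0, 1.0)
    if was_uint8:
        return np.round(out * 255.0).astype(np.uint8)
    return out


def gamma_decode(G_chan: np.ndarray | float, gamma: float = 2.2):
    """Screen value -> linear sensor value: D = 255 * (G/255)**gamma."""
    G = np.asarray(G_chan, dtype=float)
    out = 255.0 * (G / 255.0) ** gamma
    return float(out) if np.isscalar(G_chan) else out


def gamma_encode(D_chan: np.ndarray | float, gamma: float = 2.2):
    """Linear sensor value -> screen value: G = 255 * (D/255)**(1/gamma)."""
    D = np.asarray(D_chan, dtype=float)
    out = 255.0 * (D / 255.0) ** (1.0 / gamma)
    return float(out) if np.isscalar(D_chan) else out


def distance_calibrate(
    D2: np.ndarray, params: DistanceCalibParams
) -> np.ndarray:
    """Correct linear channels of an image shot delta_distance away from
    the reference: C_D2 = clip(D2 * tau**(delta_distance/5), 0, 255).

    Light falls off with distance, so an image shot farther than the
    reference (positive delta) is brightened by tau per 5 cm.
    """
    D2 = np.asarray(D2, dtype=float)
    factor = params.tau ** (params.delta_distance / 5.0)
    return np.clip(D2 * factor, 0.0, 255.0)


def distance_calibrate_image(
    image: np.ndarray, params: DistanceCalibParams
) -> np.ndarray:
    """Gamma-decode an 8-bit image, apply the distance correction in
    linear-light space, and re-encode.  Returns the same dtype as the input.
    """
    img, was_uint8 = _as_float_rgb(image)
    D2 = gamma_decode(img * 255.0, params.gamma)
    C_D2 = distance_calibrate(D2, params)
    N = gamma_encode(C_D2, params.gamma) / 255.0
    if was_uint8:
        return np.round(np.clip(N, 0.0, 1.0) * 255.0).astype(np.uint8)
    return np.clip(N, 0.0, 1.0)


def distance_residual(D1: np.ndarray, C_D2: np.ndarray) -> float:
    """Mean |D1 - C_D2| between reference and calibrated linear channels."""
    D1 = np.asarray(D1, dtype=float)
    C_D2 = np.asarray(C_D2, dtype=float)
    if D1.shape != C_D2.shape:
        raise ValueError("shape mismatch between D1 and C_D2")
    return float(np.mean(np.abs(D1 - C_D2)))


def white_balance_grayworld(
    image: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gray-world white balance: per-channel gains equalize channel means.

    Returns (corrected image, gains).  Gains are mean(all)/mean(channel), so
    an image whose channels already share a mean is returned unchanged.
    """
    img, was_uint8 = _as_float_rgb(image)
    means = img.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise ValueError("cannot white balance: a channel mean is zero")
    gains = means.mean() / means
    out = np.clip(img * gains[None, None, :], 0.0, 1.0)
    if was_uint8:
        out = np.round(out * 255.0).astype(np.uint8)
    return out, gains
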