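"""Forward simulator for chip images and subject cohorts.

Every downstream module is testable without any external data because the
generator produces (a) chip scenes whose groove colors follow a
Beer-Lambert-style concentration -> absorbance -> RGB map, rendered through
a camera model with spatially varying illumination, exponential distance
attenuation, auto-exposure gain, white-balance gains, sensor noise and gamma
encoding; and (b) subject cohorts spanning Fitzpatrick types II-VI with a
sigmoidal melanin-lightness link and a melanin-dependent pulse-oximeter bias.

Closure property: every corruption the camera applies has a calibration in
:mod:`scqp.image_calibration` that inverts it exactly in the noise-free,
unquantized limit.  In particular, distance attenuation uses the same
``tau**(delta/5)`` exponential family as the calibration rather than an
inverse-square law, so the inversion is exact by construction (the
discrepancy with real optics is documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from scqp.colorspace import GRAY_WEIGHTS

__all__ = [
    "DyeMap",
    "ChipScene",
    "CameraModel",
    "CohortSpec",
    "FixtureBundle",
    "generate_chip_scene",
    "generate_gradient_scene",
    "make_illumination_gradient",
    "render",
    "generate_cohort",
    "generate_worked_fixture",
    "FIXTURE_CONCENTRATIONS",
]

# Fixture row concentrations, ug/mL; every row carries the same ladder.
FIXTURE_CONCENTRATIONS = (0.0, 5.0, 10.0, 20.0, 50.0, 100.0)

FITZPATRICK_TYPES = ("II", "III", "IV", "V", "VI")
# Stratum means/sd of spectrophotometer L* per Fitzpatrick phototype.
FITZPATRICK_L_MEAN = {"II": 67.0, "III": 59.0, "IV": 50.0, "V": 40.0, "VI": 30.0}
FITZPATRICK_L_SD = 2.5


@dataclass(frozen=True)
class DyeMap:
    """Concentration -> reflectance map, channel = base * 10**(-k * conc).

    Defaults emulate a red (green-absorbing) dye on a light well bottom:
    the green extinction dominates so the 1 - G/V signal rises with
    concentration while V (the red channel) stays nearly constant.
    """

    base: tuple[float, float, float] = (0.90, 0.88, 0.86)
    k: tuple[float, float, float] = (0.0002, 0.0025, 0.0006)

    def reflectance(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        base = np.asarray(self.base)
        k = np.asarray(self.k)
        return base[None, :] * 10.0 ** (-np.outer(conc.ravel(), k))


@dataclass(frozen=True)
class ChipScene:
    """Reflectance scene (float HxWx3 in [0,1]) with ground-truth geometry."""

    image: np.ndarray
    concentrations: np.ndarray  # (6, 6)
    centers: np.ndarray  # (36, 2) row-major (row_px, col_px) groove centers
    boxes: np.ndarray  # (36, 4) half-open (r0, c0, r1, c1) inner-groove boxes
    groove_side_px: int
    rotation_deg: float = 0.0


def generate_chip_scene(
    concentrations: np.ndarray,
    dye_map: DyeMap | None = None,
    *,
    cell_px: int = 50,
    groove_fraction: float = 0.62,
    background: float = 0.18,
    margin_px: int = 30,
    rotation_deg: float = 0.0,
) -> ChipScene:
    """Render a 6x6 groove chip as a flat reflectance scene.

    Grooves are squares of ``groove_fraction * cell_px`` side (the physical
    chip has 5 mm grooves on a slightly wider pitch) on a dark background
    (the study's black-background operating point).  ``rotation_deg``
    rotates every groove square about the chip center, for robustness tests
    of the grid detector.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape != (6, 6):
        raise ValueError("expected a 6x6 concentration matrix")
    dye = dye_map or DyeMap()
    colors = dye.reflectance(conc).reshape(6, 6, 3)

    side = int(round(groove_fraction * cell_px))
    size = 6 * cell_px + 2 * margin_px
    img = np.full((size, size, 3), background, dtype=float)
    center = (size - 1) / 2.0
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])

    centers = np.empty((36, 2))
    boxes = np.empty((36, 4), dtype=int)
    rr, cc = np.mgrid[0:size, 0:size]
    for i in range(6):
        for j in range(6):
            cy = margin_px + (i + 0.5) * cell_px
            cx = margin_px + (j + 0.5) * cell_px
            cy, cx = rot @ (np.array([cy, cx]) - center) + center
            idx = i * 6 + j
            centers[idx] = (cy, cx)
            # paint the rotated square: |coords in groove frame| <= side/2
            dy, dx = rr - cy, cc - cx
            u = rot[0, 0] * dy + rot[1, 0] * dx
            w = rot[0, 1] * dy + rot[1, 1] * dx
            mask = (np.abs(u) <= side / 2) & (np.abs(w) <= side / 2)
            img[mask] = colors[i, j]
            inner = side * 0.6 / 2
            boxes[idx] = (
                int(np.ceil(cy - inner)), int(np.ceil(cx - inner)),
                int(np.floor(cy + inner)) + 1, int(np.floor(cx + inner)) + 1,
            )
    return ChipScene(
        image=img, concentrations=conc, centers=centers, boxes=boxes,
        groove_side_px=side, rotation_deg=rotation_deg,
    )


def make_illumination_gradient(
    shape: tuple[int, int],
    *,
    lo: float = 0.45,
    hi: float = 1.0,
    axis: int = 1,
    kind: str = "linear",
) -> np.ndarray:
    """Smooth multiplicative illumination field in [lo, hi].

    ``kind='linear'`` ramps along ``axis``; ``kind='corner'`` darkens
    radially toward one corner (a lamp off to one side).
    """
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("need 0 < lo <= hi <= 1")
    h, w = shape
    if kind == "linear":
        ramp = np.linspace(lo, hi, shape[axis])
        field_ = np.tile(ramp, (shape[1 - axis], 1))
        return field_ if axis == 1 else field_.T
    if kind == "corner":
        rr, cc = np.mgrid[0:h, 0:w]
        d = np.hypot(rr / h, cc / w) / np.sqrt(2.0)
        return hi - (hi - lo) * d
    raise ValueError(f"unknown gradient kind {kind!r}")


def generate_gradient_scene(
    size: int = 1600, reflectance: float = 0.7,
    lo: float = 0.45, hi: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-reflectance scene under a linear illumination ramp.

    The benchmark scene for the evenness calibration: every value-channel
    variation in the render is illumination, so the residual V spread after
    calibration measures the degree of equalization directly.  The default
    size matches the resolution regime the surround scales (20/72/250 px)
    are meant for.  Returns ``(scene, illumination)``.
    """
    illum = make_illumination_gradient((size, size), lo=lo, hi=hi)
    scene = np.full((size, size, 3), reflectance)
    return scene, illum


@dataclass(frozen=True)
class CameraModel:
    """Forward camera model applied to a reflectance scene.

    Pixel pipeline (linear-light space, then gamma encoding)::

        linear = scene * illumination * tau**(-(d - d_ref)/5) * gain * wb
        image  = (clip(linear + noise)) ** (1/gamma)

    ``auto_exposure`` emulates background-dependent exposure: the gain is
    0.5 / (mean scene luminance), clipped to [0.5, 2].
    """

    gamma: float = 2.2
    illumination: np.ndarray | None = None  # HxW in (0, 1]; None = flat 1.0
    distance_cm: float = 30.0
    reference_distance_cm: float = 30.0
    tau: float = 1.1
    auto_exposure: bool = False
    noise_sigma: float = 0.0
    wb_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def delta_distance(self) -> float:
        return self.distance_cm - self.reference_distance_cm

    def at_distance(self, distance_cm: float) -> "CameraModel":
        return replace(self, distance_cm=distance_cm)


def render(
    scene: np.ndarray,
    camera: CameraModel,
    seed: int | None = None,
    *,
    quantize: bool = True,
) -> tuple[np.ndarray, dict]:
    """Render a reflectance scene through the camera model.

    Returns ``(image, metadata)``.  With ``quantize=True`` the image is
    8-bit; ``quantize=False`` keeps float precision (used by the noise-free
    closure checks, where 8-bit rounding would dominate the residual).
    The metadata sidecar records distance, gain, gamma, tau and seed.
    """
    scene = np.asarray(scene, dtype=float)
    if scene.ndim != 3 or scene.shape[2] != 3:
        raise ValueError("expected an HxWx3 scene")
    if scene.min() < 0.0 or scene.max() > 1.0:
        raise ValueError("scene reflectances must lie in [0, 1]")
    linear = scene.copy()
    if camera.illumination is not None:
        illum = np.asarray(camera.illumination, dtype=float)
        if illum.shape != scene.shape[:2]:
            raise ValueError("illumination field shape mismatch")
        linear = linear * illum[:, :, None]
    linear = linear * camera.tau ** (-camera.delta_distance / 5.0)
    gain = 1.0
    if camera.auto_exposure:
        lum = float(np.tensordot(linear, GRAY_WEIGHTS, axes=([2], [0])).mean())
        gain = float(np.clip(0.5 / max(lum, 1e-9), 0.5, 2.0))
        # highlight-protecting metering: never push the brightest pixel
        # into channel clipping (blown highlights carry no color signal)
        peak = float(linear.max())
        if peak > 0:
            gain = min(gain, 0.98 / peak)
    linear = linear * gain
    linear = linear * np.asarray(camera.wb_gains)[None, None, :]
    if camera.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        linear = linear + rng.normal(0.0, camera.noise_sigma, linear.shape)
    linear = np.clip(linear, 0.0, 1.0)
    encoded = linear ** (1.0 / camera.gamma)
    if quantize:
        image = np.round(encoded * 255.0).astype(np.uint8)
    else:
        image = encoded
    meta = {
        "distance_cm": camera.distance_cm,
        "reference_distance_cm": camera.reference_distance_cm,
        "tau": camera.tau,
        "gamma": camera.gamma,
        "auto_gain": gain,
        "wb_gains": list(camera.wb_gains),
        "noise_sigma": camera.noise_sigma,
        "seed": seed,
        "quantized": bool(quantize),
    }
    return image, meta


# --------------------------------------------------------------------------
# Subject cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for a synthetic oximetry cohort.

    The defaults mirror the study conditions: 97 samples across Fitzpatrick
    II-VI, a sigmoidal melanin (M index) vs 1/L* link, a CCHD/NCCHD SpO2
    mixture, and a pulse oximeter that underestimates SpO2 in proportion to
    melanin above a light-skin reference.
    """

    n: int = 97
    fitzpatrick_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    # exact per-stratum counts (II..VI); overrides the probabilities when set
    fitzpatrick_counts: tuple[int, ...] | None = None
    # logistic link: M = m_lo + (m_hi - m_lo) / (1 + exp(-slope*(1/L - x0)))
    m_lo: float = 10.0
    m_hi: float = 75.0
    link_x0: float = 0.022
    link_slope: float = 250.0
    m_noise_sd: float = 1.5
    # SpO2 mixture: CCHD-like low component and NCCHD-like normal component
    frac_low_spo2: float = 0.3
    spo2_low_mean: float = 85.0
    spo2_low_sd: float = 4.0
    spo2_normal_mean: float = 97.5
    spo2_normal_sd: float = 1.2
    # melanin-dependent oximeter bias: F = A - bias*(M - m_ref) + noise
    oximeter_bias: float = 0.08
    m_ref: float = 30.0
    oximeter_noise_sd: float = 0.2
    # imaged tone = affine distortion of standard tone + ISO shift + noise
    tone_distortion: tuple[tuple[float, float], ...] = (
        (0.90, 5.0),   # L_s = 0.90 L + 5 + iso_term + noise
        (1.05, 1.0),   # a_s
        (0.95, -2.0),  # b_s
    )
    iso_coef: float = 0.004  # per ISO unit above 200, added to L_s
    tone_noise_sd: float = 0.5
    # lip features P_j = lip_coefs[j]*A + lip_offsets[j] + noise
    lip_coefs: tuple[float, ...] = (0.8, -0.5, 0.3)
    lip_offsets: tuple[float, ...] = (10.0, 150.0, 40.0)
    lip_noise_sd: float = 0.3
    # pCO2 = pco2_weights . T + pco2_bias + noise, T ~ N(0, 1) features
    pco2_weights: tuple[float, ...] = (6.0, -3.5, 2.0)
    pco2_bias: float = 41.0
    pco2_noise_sd: float = 0.5
    seed: int = 20240101

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be positive")
        p = np.asarray(self.fitzpatrick_probs, dtype=float)
        if len(p) != 5 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("fitzpatrick_probs must be 5 non-negative "
                             "values summing to 1")
        if not (0.0 <= self.frac_low_spo2 <= 1.0):
            raise ValueError("frac_low_spo2 outside [0, 1]")
        if self.fitzpatrick_counts is not None:
            c = self.fitzpatrick_counts
            if len(c) != 5 or any(x < 0 for x in c) or sum(c) != self.n:
                raise ValueError("fitzpatrick_counts must be 5 non-negative "
                                 "integers summing to n")


def melanin_from_lightness(inv_L: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Noise-free sigmoidal link from 1/L* to the M index."""
    inv_L = np.asarray(inv_L, dtype=float)
    return spec.m_lo + (spec.m_hi - spec.m_lo) / (
        1.0 + np.exp(-spec.link_slope * (inv_L - spec.link_x0))
    )


def generate_cohort(spec: CohortSpec | None = None):
    """Draw a cohort; returns ``(DataFrame, truth)``.

    The DataFrame holds the observables a study would record (one row per
    sample); ``truth`` holds the generating quantities needed by parameter
    recovery tests (noise-free melanin, generating weights, masks).
    Generation is bit-reproducible for a fixed spec (all randomness flows
    through one seeded generator).
    """
    import pandas as pd

    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    if spec.fitzpatrick_counts is not None:
        fitz = np.repeat(FITZPATRICK_TYPES, spec.fitzpatrick_counts)
        fitz = rng.permutation(fitz)
    else:
        fitz = rng.choice(FITZPATRICK_TYPES, size=n, p=spec.fitzpatrick_probs)
    L_star = np.array([
        rng.normal(FITZPATRICK_L_MEAN[t], FITZPATRICK_L_SD) for t in fitz
    ])
    L_star = np.clip(L_star, 20.0, 80.0)
    a_star = rng.normal(12.0, 2.0, n) + 0.08 * (60.0 - L_star)
    b_star = rng.normal(16.0, 2.0, n) + 0.10 * (60.0 - L_star)

    m_true = melanin_from_lightness(1.0 / L_star, spec)
    m_index = m_true + rng.normal(0.0, spec.m_noise_sd, n)
    m_index = np.clip(m_index, 0.5, 99.0)
    reflectance_655 = 10.0 ** (-m_index / 100.0)

    low = rng.random(n) < spec.frac_low_spo2
    gold = np.where(
        low,
        rng.normal(spec.spo2_low_mean, spec.spo2_low_sd, n),
        rng.normal(spec.spo2_normal_mean, spec.spo2_normal_sd, n),
    )
    gold = np.clip(gold, 60.0, 100.0)

    oximeter = gold - spec.oximeter_bias * (m_index - spec.m_ref)
    oximeter = oximeter + rng.normal(0.0, spec.oximeter_noise_sd, n)
    oximeter = np.clip(oximeter, 0.0, 100.0)

    iso = rng.choice([100, 200, 400, 800], size=n)
    iso_term = spec.iso_coef * (iso - 200)
    (sL, oL), (sa, oa), (sb, ob) = spec.tone_distortion
    tone_noise = rng.normal(0.0, spec.tone_noise_sd, (n, 3))
    L_s = sL * L_star + oL + iso_term + tone_noise[:, 0]
    a_s = sa * a_star + oa + tone_noise[:, 1]
    b_s = sb * b_star + ob + tone_noise[:, 2]
    # imaged G/B channels derived from the imaged tone (8-bit scale)
    G_s = np.clip(2.1 * L_s - 1.1 * a_s + 30.0
                  + rng.normal(0.0, spec.tone_noise_sd, n), 0, 255)
    B_s = np.clip(2.0 * L_s - 1.2 * b_s + 25.0
                  + rng.normal(0.0, spec.tone_noise_sd, n), 0, 255)

    lip = {}
    for j, (c, o) in enumerate(zip(spec.lip_coefs, spec.lip_offsets), start=1):
        lip[f"lip_p{j}"] = c * gold + o + rng.normal(0.0, spec.lip_noise_sd, n)

    T = rng.standard_normal((n, len(spec.pco2_weights)))
    pco2 = (T @ np.asarray(spec.pco2_weights) + spec.pco2_bias
            + rng.normal(0.0, spec.pco2_noise_sd, n))
    pco2 = np.clip(pco2, 15.0, 90.0)

    df = pd.DataFrame({
        "subject": np.arange(n),
        "fitzpatrick": fitz,
        "L_star": L_star, "a_star": a_star, "b_star": b_star,
        "m_index": m_index,
        "reflectance_655": reflectance_655,
        "oximeter_index": oximeter,
        "gold_spo2": gold,
        "iso": iso,
        "L_s": L_s, "a_s": a_s, "b_s": b_s, "G_s": G_s, "B_s": B_s,
        **lip,
        "pco2_gold": pco2,
    })
    for j in range(len(spec.pco2_weights)):
        df[f"pco2_t{j + 1}"] = T[:, j]

    truth = {
        "m_true": m_true,
        "oximeter_bias": spec.oximeter_bias,
        "m_ref": spec.m_ref,
        "spo2_low_mask": low,
        "lip_coefs": np.asarray(spec.lip_coefs),
        "pco2_weights": np.asarray(spec.pco2_weights),
        "pco2_bias": spec.pco2_bias,
        "tone_distortion": spec.tone_distortion,
        "iso_coef": spec.iso_coef,
    }
    return df, truth


# --------------------------------------------------------------------------
# Worked fixture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureBundle:
    """Deterministic worked-example bundle used across the test suite.

    ``images`` maps (illumination, distance_cm) -> (uint8 image, metadata);
    illumination is 'flat' or 'gradient'.  The reference condition is
    ('flat', 30.0).  ``cohort`` is a 30-subject frame with >= 4 subjects per
    Fitzpatrick stratum II-VI.
    """

    scene: ChipScene
    images: dict
    cohort: object
    cohort_truth: dict
    camera_tau: float
    camera_gamma: float
    reference_key: tuple = ("flat", 30.0)


def generate_worked_fixture(seed: int = 20240101) -> FixtureBundle:
    """Regenerate the worked fixture bit-identically for a given seed.

    One chip (rows all carrying the 0-100 ug/mL ladder) imaged under
    2 illuminations x 2 distances with mild sensor noise and auto-exposure,
    plus a 30-subject cohort balanced across Fitzpatrick II-VI.
    """
    conc = np.tile(np.asarray(FIXTURE_CONCENTRATIONS), (6, 1))
    scene = generate_chip_scene(conc)
    shape = scene.image.shape[:2]
    illums = {
        "flat": None,
        "gradient": make_illumination_gradient(shape, lo=0.45, hi=1.0,
                                               kind="corner"),
    }
    tau, gamma = 1.1, 2.2
    images = {}
    for name, illum in illums.items():
        for k, dist in enumerate((30.0, 35.0)):
            camera = CameraModel(
                gamma=gamma, illumination=illum, distance_cm=dist,
                reference_distance_cm=30.0, tau=tau,
                auto_exposure=(name, dist) != ("flat", 30.0),
                noise_sigma=0.003,
            )
            img, meta = render(scene.image, camera,
                               seed=seed + 17 * k + (name == "gradient"))
            images[(name, dist)] = (img, meta)

    # balanced by construction: exactly 6 subjects per stratum II-VI
    cohort_spec = CohortSpec(n=30, seed=seed,
                             fitzpatrick_counts=(6, 6, 6, 6, 6))
    df, truth = generate_cohort(cohort_spec)
    return FixtureBundle(
        scene=scene, images=images, cohort=df, cohort_truth=truth,
        camera_tau=tau, camera_gamma=gamma,
    )
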