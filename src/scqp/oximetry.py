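"""Skin-tone-corrected oximetry: the interconnected correction system.

Pulse oximeters systematically underestimate SpO2 in subjects with higher
melanin content.  The correction system models that bias and removes it in
three linked stages:

1. **Oximeter correction** — a linear model of the gold-standard SpO2 (A,
   arterial blood gas) on the oximeter index (F), the spectrophotometer
   skin tone (L*, a*, b*) and the melanin index (M).  Its output, the
   corrected oximeter index, becomes the reference for the camera model.
2. **Color correction** — four linear models that map the smartphone-imaged
   tone (L_s*, a_s*, b_s*, G_s, B_s) plus the camera ISO (or the HSV value
   V where ISO is unavailable) back to the instrument-grade tone
   (L*, a*, b*, M), so later measurements need no spectrophotometer.
3. **App model** — a linear model of the corrected oximeter reference on
   standardized cross-dimensional lip color features plus the corrected
   tone, trained with noise-based training: an exactly-20% random subset of
   training rows receives additive Gaussian feature noise (sigma = 10% of
   each feature's spread), teaching the weights to tolerate environmental
   variation.  The pCO2 model shares the same structure and training.

The melanin index follows the narrow-band reflectance definition
``M = 100 * log10(1 / R_655)``, and the melanin-lightness relation is
sigmoidal in 1/L* with a linear approximation valid over mid-range tones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from scqp.models import (
    DEFAULT_SEED,
    SGDLassoRegressor,
    Standardizer,
)

__all__ = [
    "melanin_index",
    "baseline_skin_tone",
    "MelaninToneFit",
    "fit_melanin_tone_relation",
    "OximeterCorrection",
    "ColorCorrection",
    "NoiseTrainedLinearModel",
    "AppSpo2Model",
    "PCO2Model",
    "classify_hypoxemia",
    "classify_band",
    "bland_altman",
    "error_metrics",
    "train_test_split_exact",
    "run_correction_system",
    "HYPOXEMIA_CUTOFF",
]

HYPOXEMIA_CUTOFF = 95.0  # SpO2 <= 95% is the low-saturation label
INNER_SITES = ("inner_left", "inner_right")
OUTER_SITES = ("outer_left", "outer_right")

# Correction-model optimizer: full-batch proximal SGD with a token L1
# penalty.  alpha = 1e-4 keeps the Lasso-loss structure without materially
# biasing the recovered weights even under collinear tone features; the
# alpha = 0.1 setting belongs to the chip concentration models, whose
# engineered features are deliberately redundant.
_CORRECTION_FIT = dict(alpha=1e-4, learning_rate=0.1, lr_decay=1e-4,
                       epochs=20000, batch_size=None)


def melanin_index(reflectance_655):
    """M index from narrow-band (655 nm) skin reflectance.

    ``M = 100 * log10(1 / R)``; monotone decreasing in reflectance, 0 for a
    perfect reflector.  Accepts scalars or arrays in (0, 1].
    """
    r = np.asarray(reflectance_655, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r <= 0.0) or np.any(r > 1.0):
        raise ValueError("reflectance must lie in (0, 1]")
    m = 100.0 * np.log10(1.0 / r)
    return float(m) if np.isscalar(reflectance_655) else m


def baseline_skin_tone(measurements: pd.DataFrame) -> dict:
    """Standard baseline tone: mean of the inner-arm replicates.

    ``measurements`` has one row per (site, replicate) with columns
    ``site`` (inner_left / inner_right / outer_left / outer_right),
    ``L_star``, ``a_star``, ``b_star`` and ``reflectance_655``.  Both inner
    arm sites must be present (three replicates each in the standard
    protocol); outer-arm rows are accepted but ignored.
    """
    sites = set(measurements["site"].unique())
    missing = [s for s in INNER_SITES if s not in sites]
    if missing:
        raise ValueError(f"missing inner-arm site(s): {missing}")
    inner = measurements[measurements["site"].isin(INNER_SITES)]
    tone = {k: float(inner[k].mean())
            for k in ("L_star", "a_star", "b_star")}
    tone["reflectance_655"] = float(inner["reflectance_655"].mean())
    tone["m_index"] = melanin_index(tone["reflectance_655"])
    return tone


@dataclass(frozen=True)
class MelaninToneFit:
    """Sigmoidal and linear fits of the M index against 1/L*."""

    logistic_params: tuple[float, float, float, float]  # (lo, hi, slope, x0)
    logistic_r2: float
    linear_slope: float
    linear_intercept: float
    linear_r2: float

    def logistic(self, inv_L):
        lo, hi, slope, x0 = self.logistic_params
        return lo + (hi - lo) / (1.0 + np.exp(-slope * (np.asarray(inv_L) - x0)))

    def linear(self, inv_L):
        return self.linear_slope * np.asarray(inv_L) + self.linear_intercept


def fit_melanin_tone_relation(cohort: pd.DataFrame) -> MelaninToneFit:
    """Fit M vs 1/L*: a 4-parameter logistic plus its linear approximation.

    Requires at least 10 subjects spanning at least 3 Fitzpatrick types
    (when a ``fitzpatrick`` column is present) and a non-degenerate spread
    of L*.
    """
    if len(cohort) < 10:
        raise ValueError("need at least 10 subjects")
    if "fitzpatrick" in cohort and cohort["fitzpatrick"].nunique() < 3:
        raise ValueError("cohort must span at least 3 Fitzpatrick types")
    L = np.asarray(cohort["L_star"], dtype=float)
    M = np.asarray(cohort["m_index"], dtype=float)
    if np.ptp(L) == 0:
        raise ValueError("degenerate cohort: constant L*")
    x = 1.0 / L

    def logistic(xv, lo, hi, slope, x0):
        return lo + (hi - lo) / (1.0 + np.exp(-slope * (xv - x0)))

    p0 = (float(M.min()), float(M.max()),
          4.0 / max(np.ptp(x), 1e-6), float(np.median(x)))
    params, _ = optimize.curve_fit(logistic, x, M, p0=p0, maxfev=20000)
    pred = logistic(x, *params)
    ss_res = float(np.sum((M - pred) ** 2))
    ss_tot = float(np.sum((M - M.mean()) ** 2))
    lin = stats.linregress(x, M)
    return MelaninToneFit(
        logistic_params=tuple(float(p) for p in params),
        logistic_r2=1.0 - ss_res / ss_tot,
        linear_slope=float(lin.slope),
        linear_intercept=float(lin.intercept),
        linear_r2=float(lin.rvalue**2),
    )


class _LinearCorrectionBase(RegressorMixin, BaseEstimator):
    """Shared plumbing: standardize features, fit the Lasso-loss SGD model,
    expose raw-scale weights for parameter-recovery checks."""

    def __init__(self, alpha: float = _CORRECTION_FIT["alpha"],
                 seed: int = DEFAULT_SEED):
        self.alpha = alpha
        self.seed = seed

    def _fit_linear(self, X: np.ndarray, y: np.ndarray) -> SGDLassoRegressor:
        self._scaler = Standardizer().fit(X)
        cfg = dict(_CORRECTION_FIT)
        cfg["alpha"] = self.alpha
        model = SGDLassoRegressor(seed=self.seed, **cfg)
        model.fit(self._scaler.transform(X), y)
        return model

    @staticmethod
    def _raw_coef(model: SGDLassoRegressor, scaler: Standardizer):
        coef = model.coef_ / scaler.scale_
        intercept = model.intercept_ - float(coef @ scaler.mean_)
        return coef, intercept


class OximeterCorrection(_LinearCorrectionBase):
    """Linear correction of the pulse-oximeter index for skin tone.

    Model: A ~ b0 + w . [F, L*, a*, b*, M], trained against the
    gold-standard arterial SpO2.  Predictions are clipped to [0, 100]%.
    """

    FEATURES = ("oximeter_index", "L_star", "a_star", "b_star", "m_index")
    TARGET = "gold_spo2"

    def fit(self, cohort: pd.DataFrame, y=None):
        missing = [c for c in (*self.FEATURES, self.TARGET)
                   if c not in cohort]
        if missing:
            raise ValueError(f"cohort missing columns: {missing}")
        X = cohort.loc[:, self.FEATURES].to_numpy(dtype=float)
        target = cohort[self.TARGET].to_numpy(dtype=float)
        self.model_ = self._fit_linear(X, target)
        self.coef_raw_, self.intercept_raw_ = self._raw_coef(
            self.model_, self._scaler)
        self.n_features_in_ = len(self.FEATURES)
        return self

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        X = cohort.loc[:, self.FEATURES].to_numpy(dtype=float)
        pred = self.model_.predict(self._scaler.transform(X))
        return np.clip(pred, 0.0, 100.0)


class ColorCorrection(_LinearCorrectionBase):
    """Map smartphone-imaged tone back to instrument-grade tone.

    Four linear models share the features [L_s*, a_s*, b_s*, G_s, B_s, I]
    (I = camera ISO, replaced by the HSV brightness V on phones that do not
    report ISO) and predict L*, a*, b* and M respectively.
    """

    IMAGED = ("L_s", "a_s", "b_s", "G_s", "B_s")
    TARGETS = ("L_star", "a_star", "b_star", "m_index")

    def _exposure_column(self, cohort: pd.DataFrame) -> str:
        if "iso" in cohort:
            return "iso"
        if "v_brightness" in cohort:
            return "v_brightness"
        raise ValueError("cohort has neither 'iso' nor 'v_brightness'")

    def fit(self, cohort: pd.DataFrame, y=None):
        self.exposure_column_ = self._exposure_column(cohort)
        feats = (*self.IMAGED, self.exposure_column_)
        missing = [c for c in (*feats, *self.TARGETS) if c not in cohort]
        if missing:
            raise ValueError(f"cohort missing columns: {missing}")
        X = cohort.loc[:, feats].to_numpy(dtype=float)
        if X.shape[0] < X.shape[1] + 2:
            raise ValueError(
                f"underdetermined: need at least {X.shape[1] + 2} subjects"
            )
        self._scaler = Standardizer().fit(X)
        Xs = self._scaler.transform(X)
        self.models_ = {}
        self.residuals_ = {}
        cfg = dict(_CORRECTION_FIT)
        cfg["alpha"] = self.alpha
        for target in self.TARGETS:
            m = SGDLassoRegressor(seed=self.seed, **cfg)
            m.fit(Xs, cohort[target].to_numpy(dtype=float))
            self.models_[target] = m
            self.residuals_[target] = (
                cohort[target].to_numpy(dtype=float) - m.predict(Xs)
            )
        return self

    def predict(self, cohort: pd.DataFrame) -> pd.DataFrame:
        feats = (*self.IMAGED, self.exposure_column_)
        X = self._scaler.transform(cohort.loc[:, feats].to_numpy(dtype=float))
        out = {f"corrected_{t}": self.models_[t].predict(X)
               for t in self.TARGETS}
        return pd.DataFrame(out, index=cohort.index)


class NoiseTrainedLinearModel(_LinearCorrectionBase):
    """Linear model with noise-based training.

    After standardization, an exactly-``round(noise_fraction * n_train)``
    random subset of training rows (seeded) receives additive Gaussian
    feature noise with sigma = ``noise_scale`` times each feature's spread
    (unit after standardization); each observed feature is then
    t_m = o_m + n_m on the noised rows and t_m = o_m elsewhere.  The
    injection mask is recorded.  Predictions are clipped to ``clip_range``.
    """

    def __init__(self, alpha: float = _CORRECTION_FIT["alpha"],
                 noise_fraction: float = 0.2, noise_scale: float = 0.1,
                 clip_range: tuple[float, float] = (0.0, 100.0),
                 seed: int = DEFAULT_SEED):
        super().__init__(alpha=alpha, seed=seed)
        self.noise_fraction = noise_fraction
        self.noise_scale = noise_scale
        self.clip_range = clip_range

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        n = X.shape[0]
        self._scaler = Standardizer().fit(X)
        Xs = self._scaler.transform(X)
        rng = np.random.default_rng(self.seed)
        n_noisy = int(round(self.noise_fraction * n))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_noisy, replace=False)] = True
        Xs = Xs.copy()
        Xs[mask] += rng.normal(0.0, self.noise_scale,
                               (n_noisy, X.shape[1]))
        self.injection_mask_ = mask
        self.model_ = SGDLassoRegressor(
            seed=self.seed, alpha=self.alpha,
            **{k: v for k, v in _CORRECTION_FIT.items() if k != "alpha"},
        ).fit(Xs, y)
        self.coef_raw_, self.intercept_raw_ = self._raw_coef(
            self.model_, self._scaler)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        pred = self.model_.predict(self._scaler.transform(X))
        return np.clip(pred, *self.clip_range)


class AppSpo2Model(NoiseTrainedLinearModel):
    """Smartphone SpO2 model: corrected-oximeter reference regressed on
    standardized lip color features plus the corrected skin tone.

    Shares the pCO2 model's noise-based training.  Output clipped to
    [0, 100]%.
    """

    def __init__(self, alpha: float = _CORRECTION_FIT["alpha"],
                 noise_fraction: float = 0.2, noise_scale: float = 0.1,
                 seed: int = DEFAULT_SEED):
        super().__init__(alpha=alpha, noise_fraction=noise_fraction,
                         noise_scale=noise_scale, clip_range=(0.0, 100.0),
                         seed=seed)


class PCO2Model(NoiseTrainedLinearModel):
    """pCO2 model: f . T + b1 on standardized cross-dimensional features,
    noise-based training, output clipped to the physiological [10, 100] mmHg.
    """

    def __init__(self, alpha: float = _CORRECTION_FIT["alpha"],
                 noise_fraction: float = 0.2, noise_scale: float = 0.1,
                 seed: int = DEFAULT_SEED):
        super().__init__(alpha=alpha, noise_fraction=noise_fraction,
                         noise_scale=noise_scale, clip_range=(10.0, 100.0),
                         seed=seed)


def classify_hypoxemia(spo2) -> np.ndarray:
    """'low' iff SpO2 <= 95%, else 'normal'.  Input must lie in [0, 100]."""
    s = np.asarray(spo2, dtype=float)
    if np.any(~np.isfinite(s)) or np.any((s < 0) | (s > 100)):
        raise ValueError("SpO2 outside [0, 100]")
    out = np.where(s <= HYPOXEMIA_CUTOFF, "low", "normal")
    return out.item() if np.isscalar(spo2) else out


def classify_band(spo2) -> np.ndarray:
    """Three-band SpO2 label: '<95', '[95,97)' or '[97,100]'."""
    s = np.asarray(spo2, dtype=float)
    if np.any(~np.isfinite(s)) or np.any((s < 0) | (s > 100)):
        raise ValueError("SpO2 outside [0, 100]")
    out = np.where(s < 95.0, "<95", np.where(s < 97.0, "[95,97)", "[97,100]"))
    return out.item() if np.isscalar(spo2) else out


def bland_altman(x, y) -> dict:
    """Agreement statistics between two paired methods.

    Sign convention: differences are (method under test) minus (reference),
    i.e. first argument minus second.  Returns bias and the 95% limits of
    agreement bias +/- 1.96 * sd(differences).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd}


def error_metrics(x, y) -> dict:
    """Mean absolute error and RMSE between paired measurements."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    d = x - y
    return {"mean_abs_error": float(np.mean(np.abs(d))),
            "rmse": float(np.sqrt(np.mean(d**2)))}


def train_test_split_exact(
    n: int, n_train: int, n_test: int, seed: int = DEFAULT_SEED
) -> tuple[np.ndarray, np.ndarray]:
    """Random split with exact subset sizes (study split: 58 train / 39 test)."""
    if n_train + n_test != n:
        raise ValueError(f"n_train + n_test must equal n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def run_correction_system(
    cohort: pd.DataFrame, seed: int = DEFAULT_SEED,
    lip_columns: list[str] | None = None,
) -> dict:
    """Full correction-system workflow on a cohort frame.

    Fits the oximeter correction (reference chain), the color correction,
    and the app SpO2 model on lip features plus corrected tone, then
    evaluates raw-oximeter, corrected-oximeter and app errors against the
    gold standard, overall and per Fitzpatrick stratum.
    """
    lip_columns = lip_columns or [c for c in cohort if c.startswith("lip_")]
    if not lip_columns:
        raise ValueError("cohort has no lip feature columns")

    oxi = OximeterCorrection(seed=seed).fit(cohort)
    corrected_oximeter = oxi.predict(cohort)

    color = ColorCorrection(seed=seed).fit(cohort)
    tone = color.predict(cohort)

    X_app = np.column_stack([
        cohort.loc[:, lip_columns].to_numpy(dtype=float),
        tone.to_numpy(dtype=float),
    ])
    app = AppSpo2Model(seed=seed).fit(X_app, corrected_oximeter)
    app_pred = app.predict(X_app)

    gold = cohort["gold_spo2"].to_numpy(dtype=float)
    raw = cohort["oximeter_index"].to_numpy(dtype=float)
    result = {
        "oximeter_correction": oxi,
        "color_correction": color,
        "app_model": app,
        "corrected_oximeter": corrected_oximeter,
        "app_prediction": app_pred,
        "raw_error": error_metrics(raw, gold),
        "corrected_error": error_metrics(corrected_oximeter, gold),
        "app_error": error_metrics(app_pred, gold),
    }
    if "fitzpatrick" in cohort:
        strata = {}
        for tone_type, idx in cohort.groupby("fitzpatrick").groups.items():
            loc = cohort.index.get_indexer(idx)
            strata[str(tone_type)] = {
                "raw": error_metrics(raw[loc], gold[loc]),
                "corrected": error_metrics(corrected_oximeter[loc], gold[loc]),
                "app": error_metrics(app_pred[loc], gold[loc]),
            }
        result["strata"] = strata
    return result
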