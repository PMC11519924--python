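"""Melanin index, correction system, classification and agreement stats."""

import numpy as np
import pandas as pd
import pytest

from scqp import oximetry as ox
from scqp import synthetic_data as sd


class TestMelaninIndex:
    def test_known_values(self):
        assert ox.melanin_index(1.0) == pytest.approx(0.0)
        assert ox.melanin_index(0.1) == pytest.approx(100.0)

    def test_monotone_decreasing_in_reflectance(self, rng):
        r = np.sort(rng.uniform(0.05, 1.0, 50))
        m = ox.melanin_index(r)
        assert (np.diff(m) <= 0).all()

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            ox.melanin_index(bad)


class TestBaselineSkinTone:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["site", "L_star", "a_star",
                                           "b_star", "reflectance_655"])

    def test_inner_arm_mean_outer_ignored(self):
        rows = (
            [("inner_left", 60.0, 10, 15, 0.5)] * 3
            + [("inner_right", 62.0, 10, 15, 0.5)] * 3
            + [("outer_left", 50.0, 9, 14, 0.3)] * 3
            + [("outer_right", 50.0, 9, 14, 0.3)] * 3
        )
        tone = ox.baseline_skin_tone(self._frame(rows))
        assert tone["L_star"] == pytest.approx(61.0)
        assert tone["m_index"] == pytest.approx(ox.melanin_index(0.5))

    def test_identical_replicates_passthrough(self):
        rows = [("inner_left", 55.0, 11, 16, 0.4)] * 3 + \
               [("inner_right", 55.0, 11, 16, 0.4)] * 3
        assert ox.baseline_skin_tone(self._frame(rows))["L_star"] == 55.0

    def test_missing_inner_site_rejected(self):
        rows = [("inner_left", 55.0, 11, 16, 0.4)] * 3
        with pytest.raises(ValueError, match="inner-arm"):
            ox.baseline_skin_tone(self._frame(rows))


class TestMelaninToneRelation:
    def test_noiseless_logistic_parameters_recovered(self):
        spec = sd.CohortSpec(n=120, seed=5, m_noise_sd=0.0)
        df, _ = sd.generate_cohort(spec)
        fit = ox.fit_melanin_tone_relation(df)
        lo, hi, slope, x0 = fit.logistic_params
        assert lo == pytest.approx(spec.m_lo, abs=1e-3)
        assert hi == pytest.approx(spec.m_hi, abs=1e-3)
        assert slope == pytest.approx(spec.link_slope, rel=1e-4)
        assert x0 == pytest.approx(spec.link_x0, abs=1e-6)
        assert fit.logistic_r2 == pytest.approx(1.0)

    def test_linear_approximation_strong_on_study_range(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=150, seed=6))
        fit = ox.fit_melanin_tone_relation(df)
        assert fit.linear_r2 >= 0.95

    def test_degenerate_cohort_rejected(self):
        df = pd.DataFrame({"L_star": np.full(20, 55.0),
                           "m_index": np.full(20, 30.0)})
        with pytest.raises(ValueError):
            ox.fit_melanin_tone_relation(df)


class TestOximeterCorrection:
    def test_noise_free_weight_recovery(self):
        """With an exact generating relation A = F + bias*(M - M_ref), the
        fitted raw-scale weights match the generator within 1%."""
        spec = sd.CohortSpec(n=200, seed=7, oximeter_noise_sd=0.0,
                             m_ref=15.0)
        df, _ = sd.generate_cohort(spec)
        fit = ox.OximeterCorrection().fit(df)
        assert abs(fit.coef_raw_[0] - 1.0) <= 0.01
        assert abs(fit.coef_raw_[4] - spec.oximeter_bias) <= \
            0.01 * spec.oximeter_bias

    def test_correction_reduces_error(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=200, seed=8))
        fit = ox.OximeterCorrection().fit(df)
        corrected = fit.predict(df)
        gold = df["gold_spo2"].to_numpy()
        raw_mae = np.mean(np.abs(df["oximeter_index"] - gold))
        assert np.mean(np.abs(corrected - gold)) < raw_mae

    def test_bias_free_cohort_gives_identity(self):
        df, _ = sd.generate_cohort(
            sd.CohortSpec(n=150, seed=9, oximeter_bias=0.0,
                          oximeter_noise_sd=0.0))
        fit = ox.OximeterCorrection().fit(df)
        assert fit.coef_raw_[0] == pytest.approx(1.0, abs=0.01)
        assert np.abs(fit.coef_raw_[1:]).max() < 0.01

    def test_missing_gold_standard_rejected(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=30, seed=1))
        with pytest.raises(ValueError):
            ox.OximeterCorrection().fit(df.drop(columns=["gold_spo2"]))


class TestColorCorrection:
    def test_affine_distortion_inverted(self):
        df, _ = sd.generate_cohort(
            sd.CohortSpec(n=100, seed=5, tone_noise_sd=0.0, m_noise_sd=0.0))
        fit = ox.ColorCorrection().fit(df)
        pred = fit.predict(df)
        err = np.abs(pred["corrected_L_star"].to_numpy()
                     - df["L_star"].to_numpy())
        assert err.max() < 0.1

    def test_v_brightness_fallback_without_iso(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=80, seed=6))
        df = df.drop(columns=["iso"])
        df["v_brightness"] = 60.0 + 0.3 * df["L_s"]
        fit = ox.ColorCorrection().fit(df)
        assert fit.exposure_column_ == "v_brightness"

    def test_neither_exposure_column_rejected(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=80, seed=6))
        with pytest.raises(ValueError, match="iso"):
            ox.ColorCorrection().fit(df.drop(columns=["iso"]))

    def test_underdetermined_cohort_rejected(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=97, seed=6))
        with pytest.raises(ValueError, match="underdetermined"):
            ox.ColorCorrection().fit(df.head(4))


class TestNoiseTrainedModels:
    def test_injection_mask_exact_fraction(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=97, seed=11))
        T = df.filter(like="pco2_t").to_numpy()
        fit = ox.PCO2Model(seed=4).fit(T, df["pco2_gold"])
        assert fit.injection_mask_.sum() == round(0.2 * len(df))

    def test_pco2_weight_recovery_within_5pct(self):
        spec = sd.CohortSpec(n=200, seed=11)
        df, truth = sd.generate_cohort(spec)
        T = df.filter(like="pco2_t").to_numpy()
        fit = ox.PCO2Model(seed=4).fit(T, df["pco2_gold"])
        rel = np.abs(fit.coef_raw_ - truth["pco2_weights"]) / \
            np.abs(truth["pco2_weights"])
        assert rel.max() <= 0.05

    def test_prediction_is_linear_form(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + 40.0
        fit = ox.PCO2Model(seed=1).fit(X, y)
        x0 = rng.normal(size=(1, 3))
        by_hand = (x0 @ fit.coef_raw_).item() + fit.intercept_raw_
        assert fit.predict(x0)[0] == pytest.approx(
            np.clip(by_hand, 10.0, 100.0), abs=1e-9)

    def test_fixed_seed_bit_identical_fit(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=97, seed=11))
        T = df.filter(like="pco2_t").to_numpy()
        y = df["pco2_gold"].to_numpy()
        a = ox.PCO2Model(seed=9).fit(T, y)
        b = ox.PCO2Model(seed=9).fit(T, y)
        assert np.array_equal(a.model_.coef_, b.model_.coef_)
        assert np.array_equal(a.injection_mask_, b.injection_mask_)

    def test_app_model_accuracy_and_split(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=97, seed=31))
        train, test = ox.train_test_split_exact(97, 58, 39, seed=2)
        assert len(train) == 58 and len(test) == 39
        assert np.intersect1d(train, test).size == 0
        X = df[["lip_p1", "lip_p2", "lip_p3"]].to_numpy()
        y = df["gold_spo2"].to_numpy()
        fit = ox.AppSpo2Model(seed=2).fit(X[train], y[train])
        rmse = float(np.sqrt(np.mean((fit.predict(X[test]) - y[test]) ** 2)))
        assert rmse <= 0.6

    def test_app_model_permuted_labels_negative_control(self):
        df, _ = sd.generate_cohort(sd.CohortSpec(n=200, seed=32))
        gen = np.random.default_rng(0)
        X = df[["lip_p1", "lip_p2", "lip_p3"]].to_numpy()
        y = gen.permutation(df["gold_spo2"].to_numpy())
        fit = ox.AppSpo2Model(seed=2).fit(X, y)
        rmse = float(np.sqrt(np.mean((fit.predict(X) - y) ** 2)))
        assert rmse > 0.8 * y.std()


class TestClassification:
    def test_hypoxemia_cutoff_boundaries(self):
        assert ox.classify_hypoxemia(95.0) == "low"
        assert ox.classify_hypoxemia(95.1) == "normal"
        assert ox.classify_band(95.1) == "[95,97)"
        assert ox.classify_band(100.0) == "[97,100]"
        assert ox.classify_band(94.9) == "<95"

    def test_monotone_in_spo2(self, rng):
        s = np.sort(rng.uniform(0, 100, 200))
        labels = ox.classify_hypoxemia(s)
        switch = np.flatnonzero(labels == "normal")
        assert (labels[switch.min():] == "normal").all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ox.classify_hypoxemia(101.0)


class TestAgreementStats:
    def test_identical_series(self):
        x = np.arange(10.0)
        ba = ox.bland_altman(x, x)
        assert ba == {"bias": 0.0, "loa_low": 0.0, "loa_high": 0.0}
        assert ox.error_metrics(x, x)["rmse"] == 0.0

    def test_constant_offset_sign_convention(self):
        x = np.arange(10.0)
        ba = ox.bland_altman(x + 1.0, x)
        assert ba["bias"] == pytest.approx(1.0)
        assert ba["loa_low"] == pytest.approx(1.0)

    def test_monte_carlo_matches_closed_form(self):
        gen = np.random.default_rng(99)
        d = gen.normal(0.5, 1.0, 100_000)
        ba = ox.bland_altman(d, np.zeros_like(d))
        assert ba["bias"] == pytest.approx(0.5, abs=0.02)
        assert ba["loa_low"] == pytest.approx(0.5 - 1.96, abs=0.05)
        assert ba["loa_high"] == pytest.approx(0.5 + 1.96, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ox.bland_altman([1.0, 2.0], [1.0])


class TestFullSystem:
    def test_improvements_hold_in_every_stratum(self):
        """Corrected oximeter and app predictions beat the raw oximeter
        against the gold standard overall and within each Fitzpatrick
        stratum (the inclusivity property)."""
        df, _ = sd.generate_cohort(sd.CohortSpec(n=200, seed=8))
        res = ox.run_correction_system(df, seed=3)
        assert res["corrected_error"]["mean_abs_error"] < \
            res["raw_error"]["mean_abs_error"]
        assert res["app_error"]["mean_abs_error"] < \
            res["raw_error"]["mean_abs_error"]
        for stratum, errs in res["strata"].items():
            assert errs["corrected"]["mean_abs_error"] < \
                errs["raw"]["mean_abs_error"], stratum
            assert errs["app"]["mean_abs_error"] < \
                errs["raw"]["mean_abs_error"], stratum

    def test_spo2_pco2_residuals_uncorrelated(self):
        """Independently generated SpO2 and pCO2 targets leave model
        residuals uncorrelated (|r| < 0.1 at n = 1000)."""
        df, _ = sd.generate_cohort(sd.CohortSpec(n=1000, seed=13))
        X_lip = df[["lip_p1", "lip_p2", "lip_p3"]].to_numpy()
        spo2 = ox.AppSpo2Model(seed=5).fit(X_lip, df["gold_spo2"])
        r_spo2 = spo2.predict(X_lip) - df["gold_spo2"].to_numpy()
        T = df.filter(like="pco2_t").to_numpy()
        pco2 = ox.PCO2Model(seed=5).fit(T, df["pco2_gold"])
        r_pco2 = pco2.predict(T) - df["pco2_gold"].to_numpy()
        assert abs(np.corrcoef(r_spo2, r_pco2)[0, 1]) < 0.1
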