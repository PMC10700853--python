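import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldclock import (
    BufferCondition,
    EgtaConstants,
    egta_kd,
    estimate_absolute_ca,
    fp_corrected_fold,
    free_ca,
    hill_fit,
    vant_hoff_correct,
)

CONST = EgtaConstants()


def hill_model(ca, kd, n, lo, hi):
    return lo + (hi - lo) * ca**n / (ca**n + kd**n)


class TestVantHoff:
    def test_reference_temperature_identity(self):
        assert vant_hoff_correct(10.97, -8.0, 20.0) == pytest.approx(10.97, abs=1e-12)

    def test_zero_enthalpy_leaves_constant_unchanged(self):
        assert vant_hoff_correct(10.97, 0.0, 5.0) == pytest.approx(10.97, abs=1e-12)

    def test_cold_correction_matches_direct_formula(self):
        # oracle: independent evaluation of the isochore at 15 degC
        expected = 10.97 + (-8.0) * (1 / 293.15 - 1 / 288.15) / (2.303 * 1.9872e-3)
        got = vant_hoff_correct(10.97, -8.0, 15.0)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got > 10.97  # exothermic binding tightens in the cold

    def test_literal_printed_variant_differs_off_reference(self):
        std = vant_hoff_correct(10.97, -8.0, 15.0)
        lit = vant_hoff_correct(10.97, -8.0, 15.0, literal_printed=True)
        assert std != lit
        assert vant_hoff_correct(10.97, -8.0, 20.0, literal_printed=True) == \
            pytest.approx(10.97, abs=1e-12)


class TestEgtaKd:
    def test_reference_value_against_hand_evaluation(self):
        # oracle: (1 + 10^(9.58-7.2) + 10^(9.58+8.96-14.4)) / 10^10.97
        expected = (1 + 10**2.38 + 10**4.14) / 10**10.97
        assert egta_kd(7.2, 20.0) == pytest.approx(expected, rel=1e-12)
        assert egta_kd(7.2, 20.0) == pytest.approx(1.50e-7, rel=5e-3)

    def test_strictly_decreasing_in_ph(self):
        kds = [egta_kd(ph, 20.0) for ph in (6.5, 7.0, 7.5, 8.0, 9.0)]
        assert all(a > b for a, b in zip(kds, kds[1:]))

    def test_temperature_direction_of_constants_and_kd(self):
        # every association constant grows on cooling (exothermic binding)...
        for logk, dh in ((9.58, -5.8), (8.96, -5.8), (10.97, -8.0)):
            assert vant_hoff_correct(logk, dh, 15.0) > logk
            assert vant_hoff_correct(logk, dh, 30.0) < logk
        # ...but proton competition (|dH1+dH2| = 11.6 > 8.0 = |dH_Ca|) wins,
        # so the effective Kd at fixed pH rises as temperature drops
        assert egta_kd(7.2, 15.0) > egta_kd(7.2, 20.0) > egta_kd(7.2, 30.0)

    def test_high_ph_approaches_primary_constant(self):
        # as protonation terms vanish the Kd tends to 1/KCa from above
        assert egta_kd(9.0, 20.0) > 10 ** -CONST.log_kca
        assert egta_kd(9.0, 20.0) < 1.1 * (1 + 10**0.58 + 10**0.54) * 10**-10.97


class TestFreeCa:
    def test_equal_buffers_give_kd_exactly(self):
        b = BufferCondition(5.0, 5.0, 7.2, 20.0)
        assert free_ca(b) == pytest.approx(egta_kd(7.2, 20.0), rel=1e-12)

    def test_no_bound_egta_means_no_free_ca(self):
        assert free_ca(BufferCondition(0.0, 10.0, 7.2, 20.0)) == 0.0

    def test_zero_free_egta_rejected(self):
        with pytest.raises(ValueError):
            free_ca(BufferCondition(10.0, 0.0, 7.2, 20.0))

    def test_kit_style_mixing_series_matches_direct_formula(self):
        # 10 mM CaEGTA / 10 mM EGTA kit mixtures; oracle computed inline
        kd = (1 + 10**2.38 + 10**4.14) / 10**10.97
        for ca_egta in (1.0, 2.5, 5.0, 7.5, 9.0):
            b = BufferCondition(ca_egta, 10.0 - ca_egta, 7.2, 20.0)
            assert free_ca(b) == pytest.approx(
                kd * ca_egta / (10.0 - ca_egta), rel=1e-12
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_homogeneous_of_degree_zero_in_concentrations(self, k):
        a = free_ca(BufferCondition(2.0, 8.0, 7.2, 20.0))
        b = free_ca(BufferCondition(2.0 * k, 8.0 * k, 7.2, 20.0))
        assert b == pytest.approx(a, rel=1e-9)


class TestHillFit:
    def test_round_trip_on_ideal_data(self):
        ca = np.logspace(-8.5, -5.5, 11)
        f = hill_model(ca, 150e-9, 1.9, 1.0, 10.0)
        fit = hill_fit(ca, f, f_min=1.0, f_max=10.0)
        assert fit.kd_nM == pytest.approx(150.0, rel=1e-6)
        assert fit.hill_n == pytest.approx(1.9, rel=1e-6)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-9)

    def test_half_saturation_point_equals_kd(self):
        ca = np.logspace(-8.5, -5.5, 11)
        f = hill_model(ca, 150e-9, 1.9, 1.0, 10.0)
        fit = hill_fit(ca, f, f_min=1.0, f_max=10.0)
        half = hill_model(fit.kd_nM * 1e-9, 150e-9, 1.9, 1.0, 10.0)
        assert half == pytest.approx(5.5, rel=1e-6)  # (f_min + f_max)/2

    def test_out_of_range_points_dropped_with_warning(self):
        ca = np.logspace(-9, -5, 9)
        f = hill_model(ca, 150e-9, 1.9, 1.0, 10.0)
        f[0], f[-1] = 1.0, 10.0  # saturated endpoints
        with pytest.warns(UserWarning, match="dropped"):
            fit = hill_fit(ca, f, f_min=1.0, f_max=10.0)
        assert fit.kd_nM == pytest.approx(150.0, rel=1e-4)

    def test_too_few_usable_points_rejected(self):
        ca = np.array([1e-8, 1e-7, 1e-6])
        f = np.array([1.0, 5.0, 10.0])  # two saturated out of three
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                hill_fit(ca, f, f_min=1.0, f_max=10.0)

    def test_noisy_recovery_within_ten_percent(self):
        ca = np.logspace(-8.5, -5.5, 11)
        clean = hill_model(ca, 150e-9, 1.9, 1.0, 10.0)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean * (1 + 0.05 * rng.normal(size=clean.size))
            noisy = np.clip(noisy, 1.0 + 1e-6, 10.0 - 1e-6)
            fit = hill_fit(ca, noisy, f_min=1.0, f_max=10.0)
            errs.append(abs(fit.kd_nM - 150.0) / 150.0)
        assert np.median(errs) < 0.10
        assert np.quantile(errs, 0.9) < 0.15

    def test_endpoint_cofit_option(self):
        ca = np.logspace(-8.5, -5.5, 11)
        f = hill_model(ca, 150e-9, 1.9, 1.0, 10.0)
        fit = hill_fit(ca, f, fit_endpoints=True)
        assert fit.kd_nM == pytest.approx(150.0, rel=1e-3)


class TestReporterCorrection:
    def test_printed_worked_example(self):
        fold = fp_corrected_fold(196.7, 67.1, 30.0)
        assert fold == pytest.approx(4.32, abs=0.01)
        est = estimate_absolute_ca(fold, 172.0, 218.0)
        assert est.estimated_nM == pytest.approx(370.7, abs=0.5)

    def test_fully_explained_by_brightness(self):
        assert fp_corrected_fold(67.1, 67.1, 30.0) == 0.0

    def test_simple_ratio(self):
        assert fp_corrected_fold(100.0, 0.0, 50.0) == pytest.approx(2.0)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            fp_corrected_fold(100.0, 0.0, 0.0)

    def test_fold_anchors_of_absolute_estimate(self):
        assert estimate_absolute_ca(1.0, 172, 218).estimated_nM == pytest.approx(218.0)
        assert estimate_absolute_ca(0.0, 172, 218).estimated_nM == pytest.approx(172.0)
        with pytest.raises(ValueError):
            estimate_absolute_ca(1.0, 218, 172)
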