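"""Carver-Richards dispersion, the Bloch-McConnell oracle, and exchange-fit
recovery."""

import numpy as np
import pytest

from kinetropy import cpmg
from kinetropy import synthetic as syn
from kinetropy.data_io import MethylId
from kinetropy.errors import ValidationError

M1 = MethylId(1, "I", "d1")
NU = syn.NU_CPMG_GRID_HZ


class TestR2effConversion:
    def test_reference_intensity_gives_zero(self):
        assert cpmg.r2eff_from_intensities(5.0, 5.0) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cpmg.r2eff_from_intensities(np.exp(-0.8), 1.0, 0.040) == \
            pytest.approx(20.0, rel=1e-12)

    def test_intensity_above_guard_flagged(self):
        r = cpmg.r2eff_from_intensities(np.array([3.0]), np.array([1.0]))
        assert np.isnan(r[0])

    def test_replicates_set_per_point_sd(self):
        disp, _ = syn.gen_dispersion({M1: (0.05, 1000.0, 2.0, 10.0)},
                                     noise_frac=0.02, seed=5)
        curve = cpmg.dispersion_curves(disp)[M1]
        assert (curve["r2eff_sd"] > 0).all()
        # replicate rows retained: 11 grid + 3 replicate points per field
        assert len(curve) == 2 * (len(NU) + 3)


class TestCarverRichards:
    def test_no_shift_difference_reduces_to_intrinsic_rate(self):
        r = cpmg.carver_richards(NU, 11.0, 0.05, 1000.0, 0.0)
        np.testing.assert_allclose(r, 11.0)
        dw = cpmg.dw_ppm_to_rad(2.0, 850.0)
        r2 = cpmg.carver_richards(NU, 11.0, 0.0, 1000.0, dw)
        np.testing.assert_allclose(r2, 11.0)

    def test_refocusing_limit(self):
        dw = cpmg.dw_ppm_to_rad(2.0, 850.0)
        high = cpmg.carver_richards(np.array([1e6]), 10.0, 0.05, 1000.0, dw)
        assert high[0] == pytest.approx(10.0, abs=1e-3)

    def test_monotone_non_increasing_in_nu(self):
        # strictly monotone in fast/intermediate exchange; in slow exchange
        # (k_ex << dw) the curve genuinely ripples where the pulsing rate
        # resonates with dw, so only approximate monotonicity (ripple below
        # 5% of the dispersion amplitude) is required there
        for pb in (0.02, 0.1):
            for kex in (200.0, 1000.0, 3000.0):
                for dwppm in (1.0, 3.0):
                    dw = cpmg.dw_ppm_to_rad(dwppm, 850.0)
                    r = cpmg.carver_richards(NU, 10.0, pb, kex, dw)
                    rex_amp = r[0] - 10.0
                    if kex >= dw:
                        assert np.all(np.diff(r) <= 1e-9)
                    else:
                        assert np.all(np.diff(r) <= 0.05 * rex_amp)

    def test_fast_exchange_plateau(self):
        # kex >> dw: low-nu plateau approaches R2_0 + pA pB dw^2 / kex
        pb, kex = 0.05, 20000.0
        dw = cpmg.dw_ppm_to_rad(1.0, 700.0)
        rex_expect = (1 - pb) * pb * dw ** 2 / kex
        r = cpmg.carver_richards(np.array([10.0]), 10.0, pb, kex, dw)
        assert r[0] - 10.0 == pytest.approx(rex_expect, rel=0.02)


class TestBlochMcConnell:
    def test_no_shift_difference_exact(self):
        r = cpmg.bloch_mcconnell_r2eff(NU, 12.0, 0.05, 1000.0, 0.0)
        np.testing.assert_allclose(r, 12.0, rtol=1e-10)

    def test_zero_minor_population_exact(self):
        dw = cpmg.dw_ppm_to_rad(2.0, 850.0)
        r = cpmg.bloch_mcconnell_r2eff(NU, 12.0, 0.0, 1000.0, dw)
        np.testing.assert_allclose(r, 12.0, rtol=1e-10)

    def test_agrees_with_closed_form_on_grid(self):
        # central correctness property: closed form vs numerical propagation
        worst = 0.0
        for pb in (0.02, 0.05, 0.1):
            for kex in (200.0, 1000.0, 3000.0):
                for dwppm in (1.0, 2.0, 3.0):
                    dw = cpmg.dw_ppm_to_rad(dwppm, 850.0)
                    cr = cpmg.carver_richards(NU, 10.0, pb, kex, dw)
                    bm = cpmg.bloch_mcconnell_r2eff(NU, 10.0, pb, kex, dw)
                    rex_amp = cr[0] - 10.0
                    if rex_amp > 1e-6:
                        worst = max(worst,
                                    float(np.max(np.abs(cr - bm)) / rex_amp))
        assert worst < 0.005


class TestFitDispersion:
    def test_noiseless_recovery_three_digits(self):
        disp, _ = syn.gen_dispersion({M1: (0.05, 1000.0, 2.0, 10.0)},
                                     noise_frac=0.0)
        fit = cpmg.fit_dispersion(cpmg.dispersion_curves(disp)[M1])
        assert fit.exchange_detected
        assert fit.p_b == pytest.approx(0.05, rel=1e-3)
        assert fit.k_ex == pytest.approx(1000.0, rel=1e-3)
        assert fit.dw_ppm == pytest.approx(2.0, rel=1e-3)
        for fld, r20 in fit.r2_0.items():
            assert r20 == pytest.approx(10.0, rel=1e-3)

    def test_flat_truth_not_detected(self):
        disp, _ = syn.gen_dispersion({M1: (0.0, 0.0, 0.0, 14.0)},
                                     noise_frac=0.01, seed=9)
        fit = cpmg.fit_dispersion(cpmg.dispersion_curves(disp)[M1])
        assert not fit.exchange_detected
        assert fit.r2_0[700.0] == pytest.approx(14.0, rel=0.01)

    def test_reported_shift_difference_is_magnitude(self):
        disp, _ = syn.gen_dispersion({M1: (0.05, 1000.0, 2.0, 10.0)},
                                     noise_frac=0.0)
        fit = cpmg.fit_dispersion(cpmg.dispersion_curves(disp)[M1])
        assert fit.dw_ppm >= 0
        # the closed form is even in dw: both signs give the same curve
        dw = cpmg.dw_ppm_to_rad(2.0, 850.0)
        np.testing.assert_allclose(
            cpmg.carver_richards(NU, 10.0, 0.05, 1000.0, dw),
            cpmg.carver_richards(NU, 10.0, 0.05, 1000.0, -dw), rtol=1e-12)

    def test_too_few_points_rejected(self):
        disp, _ = syn.gen_dispersion({M1: (0.05, 1000.0, 2.0, 10.0)},
                                     nu_grid_hz=[100.0, 200.0, 400.0, 800.0],
                                     replicate_nus=(), noise_frac=0.0)
        with pytest.raises(ValidationError, match=">= 8"):
            cpmg.fit_dispersion(cpmg.dispersion_curves(disp)[M1])


class TestRex:
    def test_zero_without_exchange(self):
        disp, _ = syn.gen_dispersion({M1: (0.0, 0.0, 0.0, 14.0)},
                                     noise_frac=0.0)
        fit = cpmg.fit_dispersion(cpmg.dispersion_curves(disp)[M1])
        assert cpmg.rex(fit, 850.0) == 0.0

    def test_fast_exchange_closed_form(self):
        pb, kex, dwppm = 0.05, 20000.0, 1.0
        dw = cpmg.dw_ppm_to_rad(dwppm, 850.0)
        expect = (1 - pb) * pb * dw ** 2 / kex
        got = cpmg.rex_amplitude(pb, kex, dwppm, 850.0, nu_min=10.0)
        assert got == pytest.approx(expect, rel=0.05)

    def test_increases_with_shift_difference(self):
        vals = [cpmg.rex_amplitude(0.05, 1000.0, d, 850.0)
                for d in (0.5, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(vals) > 0)
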