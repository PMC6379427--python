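"""Cross-correlated relaxation fitting, order-parameter conversion and the
O2 covariance network."""

import numpy as np
import pytest
import sympy

from kinetropy import fast_dynamics as fd
from kinetropy import synthetic as syn
from kinetropy.data_io import MethylId
from kinetropy.errors import ValidationError

M1 = MethylId(1, "I", "d1")


class TestTqSqRatio:
    def test_zero_delay(self):
        assert fd.tq_sq_ratio(25.0, 5.0, 0.0) == 0.0

    def test_vanishing_eta(self):
        assert fd.tq_sq_ratio(1e-12, 5.0, 0.02) == pytest.approx(0.0, abs=1e-10)

    def test_against_symbolic_evaluation(self):
        # independent arithmetic oracle via sympy exact evaluation
        eta, delta, T = sympy.Rational(25), sympy.Rational(5), sympy.Rational(1, 50)
        lam = sympy.sqrt(eta ** 2 + delta ** 2)
        th = sympy.tanh(lam * T)
        expected = float(sympy.Rational(3, 4) * eta * th / (lam - delta * th))
        assert fd.tq_sq_ratio(25.0, 5.0, 0.02) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_monotone_in_delay_with_asymptote(self):
        for eta, delta in [(25.0, 5.0), (80.0, 1.0), (10.0, 30.0)]:
            lam = np.hypot(eta, delta)
            # strictly increasing below tanh saturation
            t = np.linspace(1e-4, 2.5 / lam, 100)
            r = fd.tq_sq_ratio(eta, delta, t)
            assert np.all(np.diff(r) > 0)
            asym = 0.75 * eta / (lam - delta)
            assert fd.tq_sq_ratio(eta, delta, 50.0 / lam) == pytest.approx(
                asym, rel=1e-9)
            assert np.all(r < asym + 1e-9)


class TestFitEta:
    def test_noiseless_exact_recovery(self):
        dec, _ = syn.gen_tq_sq_decays({M1: (25.0, 5.0)}, noise_frac=0.0)
        g = dec.data
        cc = fd.fit_eta(g["delay_s"].to_numpy(),
                        (g["I_tq"] / g["I_sq"]).to_numpy(), n_mc=0)
        assert cc.eta == pytest.approx(25.0, rel=1e-8)
        assert cc.delta_ext == pytest.approx(5.0, rel=1e-6)

    def test_noisy_recovery_with_mc_errors(self):
        dec, _ = syn.gen_tq_sq_decays({M1: (25.0, 5.0)}, noise_frac=0.01,
                                      seed=21)
        g = dec.data
        ratio = (g["I_tq"] / g["I_sq"]).to_numpy()
        sd = np.abs(ratio) * 0.01 * np.sqrt(2.0)
        cc = fd.fit_eta(g["delay_s"].to_numpy(), ratio, sd, n_mc=200, seed=0)
        assert cc.eta == pytest.approx(25.0, rel=0.05)
        assert cc.eta_sd > 0

    def test_constant_ratio_flagged(self):
        t = np.array([0.003, 0.006, 0.009, 0.012, 0.015])
        cc = fd.fit_eta(t, np.full(5, 0.4), np.full(5, 0.004), n_mc=0)
        assert not cc.usable


class TestOrderParameter:
    def test_forward_inverse_round_trip(self):
        eta = fd.forward_eta(1.0, 25.0)
        assert fd.order_parameter(eta, 25.0).o2 == pytest.approx(1.0, rel=1e-14)

    def test_linear_in_inverse_tau_c(self):
        eta = 40.0
        o2a = fd.order_parameter(eta, 20.0).o2_raw
        o2b = fd.order_parameter(eta, 40.0).o2_raw
        assert o2a == pytest.approx(2.0 * o2b, rel=1e-14)

    def test_self_consistency_at_published_tumbling_time(self):
        eta = fd.forward_eta(0.5, 29.6)
        op = fd.order_parameter(eta, 29.6)
        assert op.o2 == pytest.approx(0.5, rel=1e-14)
        assert op.plausible

    def test_implausible_flag(self):
        eta = fd.forward_eta(1.5, 25.3)
        assert not fd.order_parameter(eta, 25.3).plausible


class TestTauCFromDls:
    def test_cubic_scaling(self):
        t1 = fd.tau_c_from_dls(2.0)
        t2 = fd.tau_c_from_dls(4.0)
        assert t2 == pytest.approx(8.0 * t1, rel=1e-12)

    def test_closed_form_inversion(self):
        from kinetropy.constants import K_BOLTZMANN
        target_ns = 25.0
        visc = 0.851e-3
        r_m = (3.0 * K_BOLTZMANN * 300.0 * target_ns * 1e-9
               / (4.0 * np.pi * visc)) ** (1.0 / 3.0)
        assert fd.tau_c_from_dls(r_m * 1e9, 300.0, visc) == pytest.approx(
            target_ns, rel=1e-10)

    def test_monotone_decreasing_in_temperature(self):
        assert fd.tau_c_from_dls(2.4, T=310.0) < fd.tau_c_from_dls(2.4, T=290.0)


class TestDeltaO2:
    def _table(self, o2_values):
        import pandas as pd
        n = len(o2_values)
        return pd.DataFrame({"residue": range(1, n + 1), "restype": ["I"] * n,
                             "methyl": ["d1"] * n, "O2": o2_values,
                             "O2_sd": [0.01] * n})

    def test_identical_tables_give_zero(self):
        t = self._table([0.5, 0.6, 0.7])
        out = fd.delta_o2(t, t)
        np.testing.assert_allclose(out["dO2"], 0.0)

    def test_uniform_rigidification_positive(self):
        a = self._table([0.5, 0.6, 0.7])
        b = self._table([0.55, 0.65, 0.75])
        out = fd.delta_o2(a, b)
        assert out["dO2"].mean() == pytest.approx(0.05)
        assert (out["dO2"] > 0).all()

    def test_empty_intersection_rejected(self):
        import pandas as pd
        a = self._table([0.5])
        b = self._table([0.5]).assign(residue=[99])
        with pytest.raises(ValidationError):
            fd.delta_o2(a, b)


class TestO2Covariance:
    def test_latent_block_recovery(self):
        n = 30
        loadings = np.zeros(n)
        loadings[:15] = 1.0
        tables, truth = syn.gen_correlated_order_params(
            n_methyls=n, latent_loadings=loadings, noise_sd=0.01, seed=8)
        net = fd.o2_covariance(tables, cutoff=0.9)
        loaded = {MethylId(*m) for m, l in zip(truth.params["methyls"],
                                               truth.params["loadings"])
                  if l != 0}
        tp = fp = fn = 0
        for a, b, _ in net.edges:
            if a in loaded and b in loaded:
                tp += 1
            else:
                fp += 1
        n_loaded_pairs = len(loaded) * (len(loaded) - 1) // 2
        fn = n_loaded_pairs - tp
        precision = tp / max(tp + fp, 1)
        recall = tp / max(tp + fn, 1)
        assert precision >= 0.9 and recall >= 0.9

    def test_matrix_symmetric_unit_diagonal(self):
        tables, _ = syn.gen_correlated_order_params(n_methyls=10,
                                                    noise_sd=0.02, seed=4)
        net = fd.o2_covariance(tables)
        p = net.pearson
        assert np.allclose(p, p.T, equal_nan=True)
        np.testing.assert_allclose(np.diag(p), 1.0)
        finite = p[np.isfinite(p)]
        assert finite.min() >= -1.0 - 1e-12 and finite.max() <= 1.0 + 1e-12

    def test_anticorrelated_pairs_excluded(self):
        loadings = np.array([1.0, 1.0, -1.0, -1.0])
        tables, _ = syn.gen_correlated_order_params(
            n_methyls=4, latent_loadings=loadings, noise_sd=0.0, seed=6)
        net = fd.o2_covariance(tables, cutoff=0.9)
        pairs = {frozenset((a.residue_number, b.residue_number))
                 for a, b, _ in net.edges}
        # only like-signed pairs survive the > 0.9 rule
        assert pairs == {frozenset((1, 2)), frozenset((3, 4))}
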