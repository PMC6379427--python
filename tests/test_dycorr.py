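"""Geometry and clustering behaviour of the DyCorr synchrony map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinetropy import dycorr
from kinetropy.cpmg import ExchangeFit
from kinetropy.data_io import MethylId
from kinetropy.errors import ValidationError


def _fit(pb, kex, detected=True):
    return ExchangeFit(p_b=pb, k_ex=kex, dw_ppm=2.0, r2_0={850.0: 10.0},
                       exchange_detected=detected)


class TestRateDecomposition:
    def test_arithmetic(self):
        rp = dycorr.rate_decomposition(_fit(0.05, 1000.0))
        assert rp.k_on == pytest.approx(50.0)
        assert rp.k_off == pytest.approx(950.0)

    def test_zero_excited_population(self):
        rp = dycorr.rate_decomposition(_fit(0.0, 800.0))
        assert rp.k_on == 0.0 and rp.k_off == 800.0

    @given(st.floats(min_value=0.0, max_value=0.5),
           st.floats(min_value=1.0, max_value=1e5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rates_sum_to_kex(self, pb, kex):
        rp = dycorr.rate_decomposition(_fit(pb, kex))
        assert rp.k_on + rp.k_off == pytest.approx(kex, rel=1e-12)

    def test_requires_detected_exchange(self):
        with pytest.raises(ValidationError):
            dycorr.rate_decomposition(_fit(0.0, 0.0, detected=False))


class TestRelativeDistance:
    def test_coincident_points(self):
        assert dycorr.relative_distance((3.0, 4.0), (3.0, 4.0)) == 0.0

    def test_axis_pair_attains_supremum(self):
        assert dycorr.relative_distance((1.0, 0.0), (0.0, 1.0)) == \
            pytest.approx(2.0, abs=1e-15)

    def test_diagonal_pair(self):
        assert dycorr.relative_distance((2.0, 2.0), (1.0, 1.0)) == \
            pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = rng.uniform(0.0, 1e4, (2, 2))
            c = rng.uniform(1e-3, 1e3)
            k1 = dycorr.relative_distance(a, b)
            k2 = dycorr.relative_distance(c * a, c * b)
            assert k2 == pytest.approx(k1, rel=1e-9)

    def test_brute_force_never_exceeds_supremum(self):
        rng = np.random.default_rng(12345)
        a = rng.uniform(0.0, 1.0, (100_000, 2)) ** 2 * 1e4
        b = rng.uniform(0.0, 1.0, (100_000, 2)) ** 2 * 1e4
        mid = 0.5 * (a + b)
        kappa = np.linalg.norm(a - b, axis=1) / np.linalg.norm(mid, axis=1)
        assert np.nanmax(kappa) <= 2.0 + 1e-9


class TestProximity:
    def test_closest(self):
        assert dycorr.proximity(0.0, 2.0, "nonlinear") == 1.0
        assert dycorr.proximity(0.0, 2.0, "linear") == 1.0

    def test_farthest(self):
        assert dycorr.proximity(2.0, 2.0, "nonlinear") == 0.0
        assert dycorr.proximity(2.0, 2.0, "linear") == 0.0

    def test_midrange_values(self):
        assert dycorr.proximity(1.0, 2.0, "nonlinear") == pytest.approx(0.25)
        assert dycorr.proximity(1.0, 2.0, "linear") == pytest.approx(0.5)

    def test_kappa_beyond_max_rejected(self):
        with pytest.raises(ValidationError):
            dycorr.proximity(1.5, 1.0)

    def test_nonlinear_strictly_decreasing(self):
        k = np.linspace(0.0, 1.8, 100)
        eta = np.array([dycorr.proximity(x, 1.8, "nonlinear") for x in k])
        assert np.all(np.diff(eta) < 0)


class TestBuildMap:
    def test_identical_rates_fully_synchronous(self):
        fits = {MethylId(i, "I", "d1"): _fit(0.05, 1000.0) for i in (1, 2, 3)}
        m = dycorr.build_map(fits)
        np.testing.assert_allclose(m.eta, 1.0)

    def test_two_clusters_separate(self):
        rng = np.random.default_rng(3)
        fits = {}
        for i in range(6):
            fits[MethylId(i + 1, "I", "d1")] = _fit(
                0.05 * (1 + 0.005 * rng.normal()),
                1000.0 * (1 + 0.005 * rng.normal()))
        for i in range(6, 12):
            fits[MethylId(i + 1, "L", "d1")] = _fit(
                0.3 * (1 + 0.005 * rng.normal()),
                120.0 * (1 + 0.005 * rng.normal()))
        m = dycorr.build_map(fits)
        idx = {mid: k for k, mid in enumerate(m.methyls)}
        within, between = [], []
        for a in fits:
            for b in fits:
                if idx[a] >= idx[b]:
                    continue
                same = (a.residue_number <= 6) == (b.residue_number <= 6)
                (within if same else between).append(m.eta[idx[a], idx[b]])
        assert min(within) > 0.9
        assert max(between) < 0.5

    def test_undetected_residues_excluded(self):
        fits = {MethylId(1, "I", "d1"): _fit(0.05, 1000.0),
                MethylId(2, "L", "d1"): _fit(0.06, 900.0),
                MethylId(3, "V", "g1"): _fit(0.0, 0.0, detected=False)}
        m = dycorr.build_map(fits)
        assert len(m.methyls) == 2
        assert m.excluded == [MethylId(3, "V", "g1")]

    def test_fewer_than_two_detected_rejected(self):
        with pytest.raises(ValidationError):
            dycorr.build_map({MethylId(1, "I", "d1"): _fit(0.05, 1000.0)})

    def test_map_invariants(self):
        rng = np.random.default_rng(7)
        pts = [dycorr.RatePoint(None, *rng.uniform(10.0, 5000.0, 2))
               for _ in range(10)]
        m = dycorr.build_map(pts)
        assert np.allclose(m.eta, m.eta.T)
        np.testing.assert_allclose(np.diag(m.eta), 1.0)
        off = m.eta[~np.eye(len(pts), dtype=bool)]
        assert off.min() >= 0.0 and off.max() <= 1.0
        assert m.kappa_m <= 2.0


class TestSynchronyClusters:
    def test_single_cluster_complete(self):
        fits = {MethylId(i, "I", "d1"): _fit(0.05, 1000.0) for i in (1, 2, 3)}
        comps = dycorr.synchrony_clusters(dycorr.build_map(fits), cutoff=0.9)
        assert len(comps) == 1 and len(comps[0]) == 3

    def test_block_structure_recovered(self):
        fits = {}
        for i in (1, 2, 3):
            fits[MethylId(i, "I", "d1")] = _fit(0.05, 1000.0 + i * 0.1)
        for i in (4, 5, 6):
            fits[MethylId(i, "L", "d1")] = _fit(0.3, 100.0 + i * 0.1)
        comps = dycorr.synchrony_clusters(dycorr.build_map(fits), cutoff=0.9)
        blocks = {frozenset(m.residue_number for m in c) for c in comps}
        assert blocks == {frozenset((1, 2, 3)), frozenset((4, 5, 6))}

    def test_unit_cutoff_gives_singletons(self):
        rng = np.random.default_rng(11)
        pts = [dycorr.RatePoint(None, *rng.uniform(10.0, 5000.0, 2))
               for _ in range(5)]
        comps = dycorr.synchrony_clusters(dycorr.build_map(pts), cutoff=1.0)
        assert all(len(c) == 1 for c in comps)
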