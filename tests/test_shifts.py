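"""Chemical-shift perturbations, CONCISE equilibrium positions and CHESCA
covariance."""

import numpy as np
import pytest

from kinetropy import shifts as sh
from kinetropy import synthetic as syn
from kinetropy.constants import R_KCAL
from kinetropy.data_io import MethylId, StateShiftTable
from kinetropy.errors import ValidationError


class TestCsp:
    def test_hand_value_carbon(self):
        assert sh.csp(0.06, 0.16, "13C") == pytest.approx(
            np.sqrt(0.0036 + 0.25 * 0.0256), rel=1e-12)

    def test_zero(self):
        assert sh.csp(0.0, 0.0, "13C") == 0.0

    def test_nucleus_scaling(self):
        c13 = sh.csp(0.0, 1.0, "13C")
        n15 = sh.csp(0.0, 1.0, "15N")
        assert c13 == pytest.approx(0.5)
        assert n15 == pytest.approx(np.sqrt(0.154))

    def test_unknown_nucleus(self):
        with pytest.raises(ValidationError):
            sh.csp(0.1, 0.1, "31P")

    def test_sign_invariance(self):
        assert sh.csp(-0.06, 0.16) == sh.csp(0.06, -0.16)


class TestMaxVectorDistance:
    def test_identical_states(self):
        prof = np.array([[0.5, 15.0]] * 4)
        assert sh.max_vector_distance(prof) == 0.0

    def test_two_state_hand_value(self):
        prof = np.array([[0.0, 10.0], [0.08, 10.08]])
        assert sh.max_vector_distance(prof) == pytest.approx(
            np.sqrt(0.08 ** 2 + (0.25 * 0.08) ** 2), rel=1e-12)

    def test_collinear_states_extreme_pair(self):
        base = np.array([0.2, 14.0])
        d = np.array([0.1, 0.4])
        prof = np.array([base, base + 0.5 * d, base + d])
        full = sh.max_vector_distance(np.array([base, base + d]))
        assert sh.max_vector_distance(prof) == pytest.approx(full, rel=1e-12)


class TestChesca:
    def test_collinear_responses_single_cluster(self):
        table, truth = syn.gen_response_groups(n_per_group=6, seed=2)
        # use only group 0 methyls: all share one response direction
        mids = {MethylId(*m) for m, g in zip(truth.params["methyls"],
                                             truth.params["groups"]) if g == 0}
        sub = StateShiftTable(
            states=table.states,
            shifts={k: v for k, v in table.shifts.items() if k[0] in mids})
        res = sh.chesca(sub, distance_cutoff=0.05)
        off = res.pearson[~np.eye(len(res.methyls), dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-9)

    def test_orthogonal_groups_block_structure(self):
        table, truth = syn.gen_response_groups(n_per_group=10, seed=7)
        res = sh.chesca(table, distance_cutoff=0.05)
        group_of = {MethylId(*m): g for m, g in
                    zip(truth.params["methyls"], truth.params["groups"])}
        idx = {m: i for i, m in enumerate(res.methyls)}
        for a in res.methyls:
            for b in res.methyls:
                if idx[a] >= idx[b]:
                    continue
                r = res.pearson[idx[a], idx[b]]
                if group_of[a] == group_of[b]:
                    assert abs(r) == pytest.approx(1.0, abs=1e-9)
                else:
                    assert abs(r) < 0.2

    def test_filter_monotone_in_cutoff(self):
        table, _ = syn.gen_response_groups(n_per_group=10, noise_ppm=0.005,
                                           seed=3)
        kept_strict = set(sh.chesca(table, distance_cutoff=0.1).methyls)
        kept_loose = set(sh.chesca(table, distance_cutoff=0.05).methyls)
        assert kept_strict <= kept_loose

    def test_too_few_retained_rejected(self):
        table, _ = syn.gen_response_groups(n_per_group=3, seed=1)
        with pytest.raises(ValidationError):
            sh.chesca(table, distance_cutoff=50.0)


class TestConcise:
    def test_noiseless_positions_exact(self):
        pops = [0.0, 0.35, 0.75, 1.0]
        table, _ = syn.gen_shift_titration(
            n_methyls=40, populations=pops, linear_fraction=1.0,
            noise_ppm=0.0, seed=9)
        res = sh.concise(table, (table.states[0], table.states[-1]))
        for st, p in zip(table.states, pops):
            assert res.positions[st] == pytest.approx(p, abs=1e-10)

    def test_nonlinear_decoys_removed(self):
        table, truth = syn.gen_shift_titration(
            n_methyls=100, linear_fraction=0.6, noise_ppm=0.0, seed=13)
        res = sh.concise(table, (table.states[0], table.states[-1]))
        linear = {MethylId(*r["methyl"]) for r in truth.params["methyls"]
                  if r["linear"]}
        decoys = {MethylId(*r["methyl"]) for r in truth.params["methyls"]
                  if not r["linear"]}
        kept = set(res.kept)
        removed_frac = len(decoys - kept) / len(decoys)
        assert removed_frac >= 0.95
        # and linear methyls are overwhelmingly retained
        assert len(linear & kept) / len(linear) >= 0.95

    def test_state_equal_to_open_basis_at_zero(self):
        pops = [0.0, 0.0, 0.5, 1.0]
        table, _ = syn.gen_shift_titration(
            n_methyls=15, populations=pops, linear_fraction=1.0,
            noise_ppm=0.0, seed=4)
        res = sh.concise(table, (table.states[0], table.states[-1]))
        assert res.positions[table.states[1]] == pytest.approx(0.0, abs=1e-10)

    def test_translation_invariance(self):
        pops = [0.0, 0.3, 0.7, 1.0]
        table, _ = syn.gen_shift_titration(
            n_methyls=10, populations=pops, linear_fraction=1.0, seed=6)
        shifted = StateShiftTable(
            states=table.states,
            shifts={k: (v[0] + 3.0, v[1] - 7.0)
                    for k, v in table.shifts.items()})
        r1 = sh.concise(table, (table.states[0], table.states[-1]))
        r2 = sh.concise(shifted, (table.states[0], table.states[-1]))
        for st in table.states:
            assert r2.positions[st] == pytest.approx(r1.positions[st],
                                                     abs=1e-9)

    def test_basis_swap_mirrors_positions(self):
        pops = [0.0, 0.3, 0.7, 1.0]
        table, _ = syn.gen_shift_titration(
            n_methyls=10, populations=pops, linear_fraction=1.0, seed=8)
        fwd = sh.concise(table, (table.states[0], table.states[-1]))
        rev = sh.concise(table, (table.states[-1], table.states[0]))
        for st in table.states:
            assert rev.positions[st] == pytest.approx(1.0 - fwd.positions[st],
                                                      abs=1e-9)

    def test_unknown_basis_rejected(self):
        table, _ = syn.gen_shift_titration(n_methyls=5, seed=1)
        with pytest.raises(ValidationError):
            sh.concise(table, ("apo", table.states[-1]))


class TestPopulationsToDdg:
    def _result(self, pops, seed=0):
        table, _ = syn.gen_shift_titration(
            n_methyls=30, populations=pops, linear_fraction=1.0,
            noise_ppm=0.002, seed=seed)
        return sh.concise(table, (table.states[0], table.states[-1])), table

    def test_reference_state_zero(self):
        res, table = self._result([0.0, 0.5, 0.5, 1.0])
        out = sh.populations_to_ddg(res, table.states[1], T=300.0)
        row = out[out["state"] == table.states[1]].iloc[0]
        assert row["ddG_kcal_mol"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_log_odds(self):
        # p = 0.75 vs reference 0.5 at 300 K: -RT ln 3
        res, table = self._result([0.0, 0.5, 0.75, 1.0], seed=5)
        out = sh.populations_to_ddg(res, table.states[1], T=300.0)
        row = out[out["state"] == table.states[2]].iloc[0]
        p = res.positions[table.states[2]]
        pr = res.positions[table.states[1]]
        expect = -R_KCAL * 300.0 * (np.log(p / (1 - p)) - np.log(pr / (1 - pr)))
        assert row["ddG_kcal_mol"] == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(-R_KCAL * 300.0 * np.log(3.0), abs=0.05)

    def test_swap_antisymmetry(self):
        res, table = self._result([0.0, 0.35, 0.65, 1.0], seed=7)
        s1, s2 = table.states[1], table.states[2]
        d12 = sh.populations_to_ddg(res, s1)
        d21 = sh.populations_to_ddg(res, s2)
        v12 = d12[d12["state"] == s2]["ddG_kcal_mol"].iloc[0]
        v21 = d21[d21["state"] == s1]["ddG_kcal_mol"].iloc[0]
        assert v12 == pytest.approx(-v21, rel=1e-9)

    def test_endpoint_positions_censored(self):
        res, table = self._result([0.0, 0.4, 0.6, 1.0], seed=2)
        out = sh.populations_to_ddg(res, table.states[1])
        first = out[out["state"] == table.states[0]].iloc[0]
        assert bool(first["censored"]) or abs(first["ddG_kcal_mol"]) < 50
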