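import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lssr import (
    FixtureSpec,
    LssrParams,
    autoncs_weight,
    delta,
    enumerate_restraints,
    generate_ncs_fixture,
    lssr_alpha,
    lssr_gradient,
    lssr_penalty,
    match_atoms,
    total_lssr,
    total_lssr_gradient,
)
from lssr.core import (
    read_restraints_json,
    read_restraints_tsv,
    restraint_lists_to_records,
    write_restraints_json,
    write_restraints_tsv,
)
from lssr.topology import build_topology

from _oracles import brute_force_pairs, brute_force_total
from conftest import build_pair_list, make_structure

DEFAULTS = LssrParams()

# printed contact-comparison rows: (r1, r2, delta at 2 d.p.)
TABLE1_ROWS = [
    (2.912, 3.000, 0.09),
    (3.765, 3.724, 0.04),
    (4.550, 4.427, 0.12),
    (5.102, 5.205, 0.10),
    (2.671, 3.051, 0.38),
    (3.783, 4.180, 0.40),
    (5.056, 5.367, 0.31),
    (4.623, 4.273, 0.35),
    (4.314, 3.918, 0.40),
]


class TestDelta:
    @pytest.mark.parametrize("r1,r2,expected", TABLE1_ROWS)
    def test_printed_contact_rows(self, r1, r2, expected):
        assert round(delta(r1, r2), 2) == expected

    def test_identity(self):
        assert delta(2.5, 2.5) == 0.0

    def test_symmetric(self):
        assert delta(1.0, 3.5) == delta(3.5, 1.0) == 2.5

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            delta(-1.0, 2.0)


class TestAlpha:
    def test_closed_form(self):
        assert lssr_alpha(0.2, 3.0) == pytest.approx(math.log(1.5), abs=1e-15)

    def test_normalization_holds(self):
        for v_max in (1.5, 2.0, 3.0, 10.0):
            p = LssrParams(sigma=0.2, v_max=v_max)
            assert lssr_penalty(0.2, p) == pytest.approx(1.0, abs=1e-12)

    def test_v_max_near_one(self):
        alpha = lssr_alpha(0.2, 1.0001)
        assert math.isfinite(alpha) and alpha > 9.0
        p = LssrParams(sigma=0.2, v_max=1.0001)
        assert lssr_penalty(0.2, p) == pytest.approx(1.0, rel=1e-9)

    def test_v_max_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            lssr_alpha(0.2, 1.0)
        with pytest.raises(ValueError):
            lssr_alpha(0.2, 0.5)

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            lssr_alpha(0.0, 3.0)


class TestPenalty:
    def test_zero_at_zero(self):
        assert lssr_penalty(0.0) == 0.0

    def test_one_at_sigma(self):
        assert lssr_penalty(0.2) == pytest.approx(1.0, abs=1e-9)

    def test_plateau_value(self):
        assert lssr_penalty(2.0) == pytest.approx(3.0, abs=1e-6)

    def test_flat_above_point_seven(self):
        assert lssr_penalty(0.7) >= 0.99 * DEFAULTS.v_max

    def test_harmonic_limit(self):
        # V/delta^2 converges to alpha*v_max/sigma^2 as delta -> 0
        limit = DEFAULTS.alpha * DEFAULTS.v_max / DEFAULTS.sigma**2
        for d in (1e-3, 1e-4, 1e-5):
            assert lssr_penalty(d) / d**2 == pytest.approx(limit, rel=1e-4)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            lssr_penalty(-0.1)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(1e-6, 1.2), st.floats(1e-6, 1.2))
    def test_strictly_monotone(self, d1, d2):
        # strict ordering tested where float precision can resolve it; the
        # plateau saturates to v_max exactly in double precision beyond ~2
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        assert lssr_penalty(lo) < lssr_penalty(hi)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_non_decreasing_everywhere(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert lssr_penalty(lo) <= lssr_penalty(hi)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 100))
    def test_bounded(self, d):
        v = lssr_penalty(d)
        assert 0.0 <= v <= DEFAULTS.v_max


class TestAutoncsWeight:
    @pytest.mark.parametrize("w,n,expected", [
        (1.0, 2, 1.0),
        (1.0, 3, 0.5),
        (2.0, 5, 0.5),
    ])
    def test_rule(self, w, n, expected):
        assert autoncs_weight(w, n) == expected

    def test_fewer_than_two_chains_rejected(self):
        with pytest.raises(ValueError):
            autoncs_weight(1.0, 1)


def _two_pair_structure(r1, r2, sep=100.0):
    """Two matched atoms per copy at controlled separations; the atoms sit in
    different residues so no bond path connects them."""
    return make_structure({
        "A": [(1, "GLY", [("CA", "C", (0, 0, 0))]),
              (2, "GLY", [("CA", "C", (r1, 0, 0))])],
        "B": [(1, "GLY", [("CA", "C", (0, sep, 0))]),
              (2, "GLY", [("CA", "C", (r2, sep, 0))])],
    })


class TestEnumerateRestraints:
    def test_beyond_cutoff_in_both_copies_excluded(self):
        s = _two_pair_structure(6.0, 6.0)
        rl = enumerate_restraints(match_atoms(s, "A", "B"), s)
        assert len(rl) == 0

    def test_within_cutoff_in_one_copy_included(self):
        s = _two_pair_structure(5.0, 6.0)
        rl = enumerate_restraints(match_atoms(s, "A", "B"), s)
        assert len(rl) == 1
        assert rl.restraints[0].delta == pytest.approx(1.0)

    def test_cutoff_is_strict(self):
        s = _two_pair_structure(5.5, 5.5)
        rl = enumerate_restraints(match_atoms(s, "A", "B"), s)
        assert len(rl) == 0

    def test_one_two_and_one_three_pairs_excluded(self, two_copy_fixture):
        s = two_copy_fixture
        rl = build_pair_list(s)
        topo = build_topology(s)
        adj = topo.adjacency
        for r in rl.restraints:
            i, j = r.idx_i, r.idx_j
            assert j not in adj[i]  # no 1-2
            assert not (adj[i] & adj[j])  # no 1-3

    def test_one_four_pairs_are_included(self, two_copy_fixture):
        # e.g. SER OG to its own backbone N (OG-CB-CA-N)
        rl = build_pair_list(two_copy_fixture)
        one_four = [r for r in rl.restraints if r.sep_class == "one_four"]
        assert one_four
        names = {
            frozenset((r.atom_i.atom_name, r.atom_j.atom_name))
            for r in one_four
            if r.atom_i.residue_key == r.atom_j.residue_key
        }
        assert frozenset(("OG", "N")) in names

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        spec = FixtureSpec(n_residues=8, n_chains=2, noise_sd=0.2, seed=seed)
        s = generate_ncs_fixture(spec)
        corr = match_atoms(s, "A", "B")
        topo = build_topology(s)
        rl = enumerate_restraints(corr, s, DEFAULTS, topology=topo)
        got = {r.pair_id: r.sep_class for r in rl.restraints}
        expected = brute_force_pairs(corr, s, topo.bonds, DEFAULTS.cutoff)
        assert got == expected

    def test_chain_order_symmetry(self, noisy_fixture):
        s = noisy_fixture
        rl_ab = enumerate_restraints(match_atoms(s, "A", "B"), s)
        rl_ba = enumerate_restraints(match_atoms(s, "B", "A"), s)
        coords = s.coords()
        pairs_ab = {
            frozenset((r.atom_i.key, r.atom_j.key)) for r in rl_ab.restraints
        }
        pairs_ba = {
            frozenset((r.atom_ip.key, r.atom_jp.key)) for r in rl_ba.restraints
        }
        assert pairs_ab == pairs_ba
        tot_ab, _ = total_lssr(rl_ab, coords)
        tot_ba, _ = total_lssr(rl_ba, coords)
        assert tot_ab == pytest.approx(tot_ba, rel=1e-12)

    def test_no_duplicate_pairs(self, noisy_fixture):
        rl = build_pair_list(noisy_fixture)
        ids = [r.pair_id for r in rl.restraints]
        assert len(ids) == len(set(ids))


class TestGradient:
    def test_zero_at_zero_delta(self, two_copy_fixture):
        rl = build_pair_list(two_copy_fixture)
        grad = total_lssr_gradient(rl, two_copy_fixture.coords())
        # deltas are zero up to float noise from the copy translation
        assert np.max(np.abs(grad)) == pytest.approx(0.0, abs=1e-9)

    def test_single_restraint_matches_vectorized(self, noisy_fixture):
        s = noisy_fixture
        rl = build_pair_list(s)
        coords = s.coords()
        total = total_lssr_gradient(rl, coords)
        rebuilt = np.zeros_like(total)
        for r in rl.restraints:
            for idx, vec in lssr_gradient(r, coords, DEFAULTS,
                                          weight=rl.weight).items():
                rebuilt[idx] += vec
        np.testing.assert_allclose(rebuilt, total, atol=1e-12)

    def test_translation_invariance_per_restraint(self, noisy_fixture):
        s = noisy_fixture
        rl = build_pair_list(s)
        coords = s.coords()
        for r in rl.restraints[:50]:
            vecs = lssr_gradient(r, coords, DEFAULTS)
            total = sum(vecs.values())
            np.testing.assert_allclose(total, np.zeros(3), atol=1e-12)

    def test_plateau_gradient_is_tiny(self):
        s1 = _two_pair_structure(3.0, 5.0)  # delta deep in plateau
        s2 = _two_pair_structure(3.0, 3.2)  # delta = sigma
        g_plateau = np.abs(
            total_lssr_gradient(build_pair_list(s1), s1.coords())
        ).max()
        g_sigma = np.abs(
            total_lssr_gradient(build_pair_list(s2), s2.coords())
        ).max()
        assert g_plateau < 1e-4 * g_sigma


class TestTotal:
    def test_exact_copy_total_zero(self, two_copy_fixture):
        rl = build_pair_list(two_copy_fixture)
        total, _ = total_lssr(rl, two_copy_fixture.coords())
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_zero_total_iff_all_deltas_zero(self, noisy_fixture):
        rl = build_pair_list(noisy_fixture)
        total, bd = total_lssr(rl, noisy_fixture.coords())
        deltas = bd[rl.label]["delta"]
        assert total > 0
        assert np.any(deltas > 0)

    def test_single_restraint_weighted(self):
        s = _two_pair_structure(3.0, 3.2)  # delta = sigma -> V = 1
        corr = match_atoms(s, "A", "B")
        rl = enumerate_restraints(corr, s, DEFAULTS, weight=2.0)
        total, _ = total_lssr(rl, s.coords())
        assert total == pytest.approx(2.0, abs=1e-9)

    def test_breakdown_resums_to_total(self, noisy_fixture):
        rl = build_pair_list(noisy_fixture)
        assert len(rl) >= 100
        total, bd = total_lssr(rl, noisy_fixture.coords())
        assert total == pytest.approx(
            float(bd[rl.label]["penalties"].sum()), rel=1e-14
        )
        oracle = brute_force_total(
            rl.restraints, DEFAULTS.sigma, DEFAULTS.v_max, rl.weight
        )
        assert total == pytest.approx(oracle, rel=1e-9)

    def test_bounded_by_n_vmax(self, noisy_fixture):
        rl = build_pair_list(noisy_fixture)
        total, _ = total_lssr(rl, noisy_fixture.coords())
        assert 0 <= total <= rl.weight * len(rl) * DEFAULTS.v_max


class TestSerialization:
    def test_tsv_round_trip_bit_exact(self, noisy_fixture, tmp_path):
        rl = build_pair_list(noisy_fixture)
        path = tmp_path / "restraints.tsv"
        write_restraints_tsv([rl], path)
        records = read_restraints_tsv(path)
        assert records == restraint_lists_to_records([rl])
        path2 = tmp_path / "again.tsv"
        write_restraints_tsv(records, path2)
        assert path.read_text() == path2.read_text()

    def test_json_round_trip(self, noisy_fixture, tmp_path):
        rl = build_pair_list(noisy_fixture)
        path = tmp_path / "restraints.json"
        write_restraints_json([rl], path)
        records = read_restraints_json(path)
        assert records == restraint_lists_to_records([rl])
        path2 = tmp_path / "again.json"
        write_restraints_json(records, path2)
        assert path.read_text() == path2.read_text()
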