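"""Contact detection, contact free energies, cooperativity and
restrained-vs-unrestrained coupling."""

import numpy as np
import pandas as pd
import pytest

from toprna.contacts_cooperativity import (
    CONTACT_CUTOFF,
    coaxial_stack,
    contact_free_energy,
    cooperativity,
    coupled_stability,
    free_energy_from_p,
    group_contact,
    mean_cooperativity,
    residue_contact,
)
from toprna.fixtures_reference import (
    place_ideal_pairs,
    synthetic_contact_streams,
)
from toprna.secstruct_topology import build_topology, parse_secondary_structure


@pytest.fixture(scope="module")
def two_helix():
    """Two 4-bp helices joined by a 1-nt linker, placed coaxially at
    consecutive helical registers (the ideal stacked geometry)."""
    ss = parse_secondary_structure("((((.((((....)))).))))")
    topo = build_topology(ss)
    h1, h2 = ss.helices
    coords = np.full((topo.n_beads, 3), np.nan)
    place_ideal_pairs(coords, topo, list(h1.pairs), start_index=0)
    place_ideal_pairs(coords, topo, list(h2.pairs), start_index=5)
    bad = np.isnan(coords[:, 0])
    coords[bad] = 200.0 + 10.0 * np.arange(bad.sum())[:, None]
    return topo, coords, h1, h2


class TestResidueContact:
    def test_distance_and_separation_rules(self, wt_topology):
        coords = np.zeros((wt_topology.n_beads, 3))
        s10 = wt_topology.bead_index(10, "S")
        s16 = wt_topology.bead_index(16, "S")
        s14 = wt_topology.bead_index(14, "S")
        coords[s16] = [13.9, 0, 0]
        assert residue_contact(coords, wt_topology, 10, 16)
        coords[s16] = [14.1, 0, 0]
        assert not residue_contact(coords, wt_topology, 10, 16)
        coords[s14] = [5.0, 0, 0]
        assert not residue_contact(coords, wt_topology, 10, 14)  # |i-j|=4

    def test_group_contact_matches_bruteforce(self, wt_topology, rng):
        el = wt_topology.secondary_structure.elements
        a, b = el["D-loop"], el["T-loop"]
        for _ in range(20):
            coords = rng.normal(
                scale=12.0, size=(wt_topology.n_beads, 3)
            )
            brute = any(
                abs(i - j) >= 5
                and np.linalg.norm(
                    coords[wt_topology.bead_index(i, "S")]
                    - coords[wt_topology.bead_index(j, "S")]
                ) < CONTACT_CUTOFF
                for i in a
                for j in b
            )
            assert group_contact(coords, wt_topology, a, b) == brute

    def test_overlapping_elements_rejected(self, wt_topology):
        coords = np.zeros((wt_topology.n_beads, 3))
        with pytest.raises(ValueError):
            group_contact(coords, wt_topology, [8, 9], [9, 10])


class TestCoaxialStack:
    def test_stacked_ideal_helices_detected(self, two_helix):
        topo, coords, h1, h2 = two_helix
        assert coaxial_stack(coords, topo, h1, h2)

    def test_perpendicular_helices_rejected(self, two_helix):
        from scipy.spatial.transform import Rotation

        topo, coords, h1, h2 = two_helix
        bent = coords.copy()
        beads2 = [b for r in h2.residues for b in topo.residue_beads(r)]
        beads2 += [
            topo.m_bead_of_pair[p] for p in h2.pairs
            if p in topo.m_bead_of_pair
        ]
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        center = coords[beads2].mean(axis=0)
        bent[beads2] = (coords[beads2] - center) @ R.T + center
        assert not coaxial_stack(bent, topo, h1, h2)

    def test_translated_apart_rejected(self, two_helix):
        topo, coords, h1, h2 = two_helix
        moved = coords.copy()
        beads2 = [b for r in h2.residues for b in topo.residue_beads(r)]
        moved[beads2] += np.array([0.0, 0.0, 10.0])
        assert not coaxial_stack(moved, topo, h1, h2)


class TestFreeEnergy:
    def test_even_odds_is_zero(self):
        stream = np.array([True, False] * 50)
        assert contact_free_energy(stream).dg_topo == pytest.approx(0.0)

    def test_log_odds_value(self):
        stream = np.array([True] * 10 + [False] * 90)
        assert contact_free_energy(stream).dg_topo == pytest.approx(
            np.log(9.0)
        )

    def test_antisymmetry(self):
        s = np.array([True] * 90 + [False] * 10)
        assert contact_free_energy(s).dg_topo == pytest.approx(
            -contact_free_energy(~s).dg_topo
        )

    def test_zero_count_reports_bound(self):
        stream = np.zeros(500, dtype=bool)
        stats = contact_free_energy(stream)
        assert stats.bounded
        assert stats.dg_topo == pytest.approx(np.log(500))

    def test_joint_set_uses_joint_frequency(self):
        df = pd.DataFrame({
            "a": [True, True, False, False] * 25,
            "b": [True, False, True, False] * 25,
        })
        joint = contact_free_energy(df, ["a", "b"])
        assert joint.p == pytest.approx(0.25)


class TestCooperativity:
    def test_independent_streams_near_one(self):
        df = synthetic_contact_streams(
            200_000, p=(0.3, 0.3), planted_c=1.0, seed=2
        )
        res = cooperativity(df, ["c1", "c2"])
        assert res.c == pytest.approx(1.0, abs=0.1)

    def test_planted_cooccurrence_recovered(self):
        df = synthetic_contact_streams(
            100_000, p=(0.1, 0.1), planted_c=10.0, seed=5
        )
        res = cooperativity(df, ["c1", "c2"])
        assert res.c == pytest.approx(10.0, rel=0.1)

    def test_zero_marginal_raises(self):
        df = pd.DataFrame({"a": [True, False], "b": [False, False]})
        with pytest.raises(ZeroDivisionError):
            cooperativity(df, ["a", "b"])

    def test_log_c_identity_with_free_energies(self):
        # ln C = dG(c1) + dG(c2) - dG(c1,c2) - ln[(1-P1)(1-P2)/(1-P12)]
        df = synthetic_contact_streams(
            50_000, p=(0.2, 0.15), planted_c=3.0, seed=8
        )
        res = cooperativity(df, ["c1", "c2"])
        g1 = contact_free_energy(df, "c1")
        g2 = contact_free_energy(df, "c2")
        g12 = contact_free_energy(df, ["c1", "c2"])
        odds = np.log(
            (1 - g1.p) * (1 - g2.p) / (1 - g12.p)
        )
        assert np.log(res.c) == pytest.approx(
            g1.dg_topo + g2.dg_topo - g12.dg_topo - odds, abs=1e-9
        )

    def test_mean_curve_excludes_rare_combinations(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "a": rng.random(2000) < 0.3,
            "b": rng.random(2000) < 0.3,
            "rare": np.arange(2000) < 5,  # joint combos <= 10 counts
        })
        curve = mean_cooperativity(df, native_contacts={"a", "b"}, n_max=3)
        used = set()
        for _, row in curve.iterrows():
            used.add((row.n_contacts, row.native))
        # no combination containing 'rare' survives the cut, so only
        # the all-native pair (a, b) remains
        assert used == {(2, True)}


class TestCoupledStability:
    def test_identical_ensembles_zero(self):
        df = synthetic_contact_streams(10_000, seed=3)
        res = coupled_stability(df, df, "c1")
        assert res.ddg_coop == pytest.approx(0.0)

    def test_probability_shift_value(self):
        unres = pd.DataFrame({"c": [True] * 10 + [False] * 90})
        restr = pd.DataFrame({"c": [True] * 50 + [False] * 50})
        res = coupled_stability(unres, restr, "c")
        assert res.ddg_coop == pytest.approx(-np.log(9.0))

    def test_refuses_contacts_bridging_active_restraint(self):
        df = pd.DataFrame({"D-loop|T-loop": [True, False] * 10})
        with pytest.raises(ValueError):
            coupled_stability(
                df, df, "D-loop|T-loop",
                restrained_loop_pairs={frozenset({"D-loop", "T-loop"})},
            )


class TestBounds:
    @pytest.mark.parametrize("p,n,expect_bounded", [
        (0.0, 100, True), (1.0, 100, True), (0.4, 100, False),
    ])
    def test_free_energy_bounds(self, p, n, expect_bounded):
        dg, bounded = free_energy_from_p(p, n)
        assert bounded == expect_bounded
        if p == 0.0:
            assert dg == pytest.approx(np.log(n))
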