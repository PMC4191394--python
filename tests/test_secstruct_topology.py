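"""Secondary-structure parsing, element naming, topology term counts
and variant editing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toprna import forcefield as ff
from toprna.cg_engine import restraint_energy_force
from toprna.fixtures_reference import (
    WT_DOTBRACKET,
    WT_SEQUENCE,
    fixture_secondary_structure,
    fixture_topology,
)
from toprna.secstruct_topology import (
    ParseError,
    PseudoknotError,
    VariantError,
    apply_variant,
    build_topology,
    make_restraints,
    parse_secondary_structure,
)

TOY_BULGE = "((((..((((....))))))))"


class TestParsing:
    def test_two_way_bulge_elements(self):
        ss = parse_secondary_structure(TOY_BULGE)
        assert len(ss.helices) == 2
        ss_elements = [
            members
            for name, members in ss.elements.items()
            if name not in {h.name for h in ss.helices}
        ]
        assert (5, 6) in [tuple(m) for m in ss_elements]

    def test_all_dots_single_element(self):
        ss = parse_secondary_structure("." * 12)
        assert len(ss.helices) == 0
        assert list(ss.elements) == ["L1"]
        assert ss.elements["L1"] == tuple(range(1, 13))

    def test_wt_cloverleaf_element_membership(self):
        ss = parse_secondary_structure(WT_SEQUENCE + "\n" + WT_DOTBRACKET)
        expected = {
            "A-stem": tuple(range(1, 8)) + tuple(range(66, 73)),
            "D-stem": tuple(range(10, 14)) + tuple(range(22, 26)),
            "AC-stem": tuple(range(27, 32)) + tuple(range(39, 44)),
            "T-stem": tuple(range(49, 54)) + tuple(range(61, 66)),
            "A/D-loop": (8, 9),
            "D-loop": tuple(range(14, 22)),
            "D/AC-linker": (26,),
            "AC-loop": tuple(range(32, 39)),
            "V-loop": tuple(range(44, 49)),
            "T-loop": tuple(range(54, 61)),
            "ACCA-tail": (73, 74, 75, 76),
        }
        for name, members in expected.items():
            assert ss.elements[name] == members, name
        # every residue in exactly one element
        seen = sorted(r for mem in ss.elements.values() for r in mem)
        assert seen == list(range(1, 77))

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(ParseError):
            parse_secondary_structure("(((..")
        with pytest.raises(ParseError):
            parse_secondary_structure("..))")

    def test_crossing_pairs_rejected(self):
        text = "# pairs n=8\n1 5\n3 7\n"
        with pytest.raises(PseudoknotError):
            parse_secondary_structure(text)

    def test_pair_list_matches_dotbracket(self):
        ss1 = parse_secondary_structure(TOY_BULGE)
        rows = "\n".join(f"{i} {j}" for i, j in ss1.pairs)
        ss2 = parse_secondary_structure(
            f"# pairs n={len(TOY_BULGE)}\n" + rows
        )
        assert ss1.pairs == ss2.pairs

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dotbracket_roundtrip(self, data):
        struct = data.draw(_nested_structures(), label="structure")
        ss = parse_secondary_structure(struct)
        assert ss.to_dotbracket() == struct


def _nested_structures():
    """Random pseudoknot-free dot-bracket strings."""

    def build(depth):
        if depth == 0:
            return st.text(alphabet=".", min_size=0, max_size=4)
        inner = build(depth - 1)
        paired = st.tuples(inner).map(lambda t: "(" + t[0] + ")")
        return st.lists(
            st.one_of(st.just("."), paired), min_size=0, max_size=4
        ).map("".join)

    return build(3).filter(lambda s: len(s) > 0)


class TestTopology:
    def test_duplex_term_counts(self):
        ss = parse_secondary_structure("(((((" + ")" * 5)
        topo = build_topology(ss, strand_breaks={(5, 6)})
        assert topo.n_beads == 35  # 30 P/S/B + 5 M
        assert sum(k == "M" for k in topo.bead_kind) == 5
        # dihedrals only along the two 5-residue helical strands:
        # 4 + 3 quadruples per strand
        assert len(topo.dihedrals) == 14

    def test_unpaired_strand_no_m_no_dihedrals(self):
        topo = build_topology(parse_secondary_structure("." * 10))
        assert topo.n_beads == 30
        assert len(topo.dihedrals) == 0
        assert not any(k == "M" for k in topo.bead_kind)

    def test_wt_bead_count(self):
        topo = fixture_topology("wt")
        assert topo.n_beads == 3 * 76 + 21
        assert len(topo.pairs) == 21

    def test_single_strand_terms_are_soft(self):
        topo = fixture_topology("wt")
        # residues of the V-loop are single stranded: all their angle
        # terms carry the soft constant
        vloop = set(topo.secondary_structure.elements["V-loop"])
        for (a, b, c), k in zip(topo.angles, topo.angle_k):
            res = {int(topo.bead_resid[i]) for i in (a, b, c)}
            if res <= vloop:
                assert k == ff.K_ANGLE_SS

    def test_sequence_independence_of_terms(self):
        s1 = parse_secondary_structure("GGGGAAAACCCC\n((((....))))")
        s2 = parse_secondary_structure("AUAUGGGGAUAU\n((((....))))")
        t1, t2 = build_topology(s1), build_topology(s2)
        assert t1.term_set() == t2.term_set()

    def test_ideal_build_has_zero_bonded_energy(self, duplex5):
        from toprna.cg_engine import energy_forces

        topo, coords = duplex5
        _, _, breakdown = energy_forces(coords, topo)
        for term in ("bond", "angle", "improper", "dihedral"):
            assert abs(breakdown[term]) < 1e-9, term


class TestVariants:
    def test_cut_removes_one_bond_and_spanning_terms(self):
        wt = fixture_topology("wt")
        cut = apply_variant(wt, "cut", residue=8)
        d_bonds = wt.term_set()["bonds"] - cut.term_set()["bonds"]
        assert len(d_bonds) == 1
        (removed,) = d_bonds
        s8 = wt.bead_index(8, "S")
        p9 = wt.bead_index(9, "P")
        assert set(removed[0]) == {s8, p9}
        assert cut.term_set()["bonds"] - wt.term_set()["bonds"] == set()
        # every removed angle/improper spans the broken link
        for key in ("angles", "impropers", "dihedrals"):
            gone = wt.term_set()[key] - cut.term_set()[key]
            for term in gone:
                assert s8 in term[0] and p9 in term[0]

    def test_cut_nonexistent_bond_rejected(self):
        wt = fixture_topology("wt")
        with pytest.raises(VariantError):
            apply_variant(wt, "cut", residue=76)
        cut = apply_variant(wt, "cut", residue=8)
        with pytest.raises(VariantError):
            apply_variant(cut, "cut", residue=8)

    def test_insert_then_delete_roundtrips(self):
        ss = fixture_secondary_structure("wt")
        plus = apply_variant(ss, "insert_loop_nt", after=46, count=1)
        back = apply_variant(plus, "delete_loop_nt", residue=47, count=1)
        assert back.pairs == ss.pairs
        assert build_topology(back).term_set() == \
            build_topology(ss).term_set()

    def test_loop_edit_inside_helix_rejected(self):
        ss = fixture_secondary_structure("wt")
        with pytest.raises(VariantError):
            apply_variant(ss, "insert_loop_nt", after=2, count=1)
        with pytest.raises(VariantError):
            apply_variant(ss, "delete_loop_nt", residue=10)

    @pytest.mark.parametrize("name,length", [
        ("vl4", 4), ("vl7", 7), ("vl9", 9), ("vl11", 11),
    ])
    def test_v_loop_length_series(self, name, length):
        ss = fixture_secondary_structure(name)
        assert len(ss.elements["V-loop"]) == length

    @pytest.mark.parametrize("name,length", [("adl3", 3), ("adl5", 5)])
    def test_ad_loop_length_series(self, name, length):
        ss = fixture_secondary_structure(name)
        assert len(ss.elements["A/D-loop"]) == length

    def test_class_ii_variant_has_v_stem(self):
        vs = fixture_secondary_structure("vs")
        names = {h.name for h in vs.helices}
        assert "V-stem" in names
        # the stem-extending pair joins the AC-stem run
        ac = next(h for h in vs.helices if h.name == "AC-stem")
        assert (26, 44) in ac.pairs

    def test_vs_nogu_drops_the_pair(self):
        vs = fixture_secondary_structure("vs")
        nogu = fixture_secondary_structure("vs-nogu")
        assert (26, 44) not in nogu.pairs
        assert len(build_topology(vs).m_bead_of_pair) == \
            len(build_topology(nogu).m_bead_of_pair) + 1


class TestRestraints:
    def test_tertiary_pair_windows(self, wt_topology):
        specs = make_restraints("tertiary_pair", (8, 14), wt_topology)
        by_window = {(s.r_min, s.r_max) for s in specs}
        assert by_window == {(5.5, 7.5), (11.0, 14.0)}
        for s in specs:
            assert s.k_min == s.k_max == 2.0
            assert s.fmax == 2.0

    def test_base_triple_window_around_reference(
        self, wt_reference, wt_topology
    ):
        specs = make_restraints(
            "base_triple", (46, (22, 13)), wt_topology,
            reference_coords=wt_reference.coords,
        )
        assert len(specs) == 4
        for s in specs:
            d = np.linalg.norm(
                wt_reference.coords[s.bead_i] - wt_reference.coords[s.bead_j]
            )
            half = 0.5 * (s.r_max - s.r_min)
            assert half in (1.0, 1.5)
            assert abs(0.5 * (s.r_min + s.r_max) - d) < 1e-9

    def test_base_triple_needs_reference(self, wt_topology):
        with pytest.raises(ValueError):
            make_restraints("base_triple", (46, (22, 13)), wt_topology)

    def test_flat_bottom_zero_at_midpoint(self, wt_topology):
        spec = make_restraints("tertiary_pair", (8, 14), wt_topology)[0]
        e, f = restraint_energy_force(
            0.5 * (spec.r_min + spec.r_max), spec
        )
        assert e == 0.0 and f == 0.0
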