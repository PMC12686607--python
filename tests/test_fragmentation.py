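"""Conjugated caps, cut-bond saturation, water attachment, four systems."""
import numpy as np
import pytest

from mfccpocket.errors import ChainDiscontinuityError
from mfccpocket.mfcc_fragmentation import (
    assign_waters, build_caps, build_fragment_systems,
)
from mfccpocket.structure_model import (
    Atom, Residue, ResidueId, Role, Structure,
)
from mfccpocket.synthetic_data import ToySpec, make_toy_complex, toy_ligand_id


@pytest.fixture(scope="module")
def pentamer():
    # ASP at 3 so the central residue carries a -1 formal charge
    return make_toy_complex(ToySpec(n_residues=5, seed=9, n_waters=0))


class TestBuildCaps:
    def test_middle_residue_full_caps(self, pentamer):
        capped = build_caps(pentamer, ResidueId("A", 3))
        assert [r.seq_number for r in capped.cap_prev] == [2]
        assert [r.seq_number for r in capped.cap_next] == [4]
        assert len(capped.cap_hydrogens) == 2
        assert {h.side for h in capped.cap_hydrogens} == {"outer_prev", "outer_next"}

    def test_n_terminal_single_cap(self, pentamer):
        capped = build_caps(pentamer, ResidueId("A", 1))
        assert capped.cap_prev == []
        assert [r.seq_number for r in capped.cap_next] == [2]
        assert len(capped.cap_hydrogens) == 1
        assert capped.cap_hydrogens[0].side == "outer_next"

    def test_c_terminal_single_cap(self, pentamer):
        capped = build_caps(pentamer, ResidueId("A", 5))
        assert capped.cap_next == []
        assert [r.seq_number for r in capped.cap_prev] == [4]
        assert len(capped.cap_hydrogens) == 1

    def test_saturating_hydrogen_geometry(self, pentamer):
        # H sits on the former bond segment at the standard length
        capped = build_caps(pentamer, ResidueId("A", 3))
        for ch in capped.cap_hydrogens:
            keep_res = pentamer.get(ch.bonded_to[0])
            removed_res = pentamer.get(ch.replaces[0])
            keep = keep_res.get_atom(ch.bonded_to[1]).position
            removed = removed_res.get_atom(ch.replaces[1]).position
            expected_len = 1.01 if ch.bonded_to[1] == "N" else 1.09
            v_h = ch.atom.position - keep
            v_bond = removed - keep
            assert np.linalg.norm(v_h) == pytest.approx(expected_len, abs=1e-3)
            cosine = v_h @ v_bond / (np.linalg.norm(v_h) * np.linalg.norm(v_bond))
            assert cosine == pytest.approx(1.0, abs=1e-9)

    def test_cap_hydrogens_are_marked(self, pentamer):
        capped = build_caps(pentamer, ResidueId("A", 3))
        for ch in capped.cap_hydrogens:
            assert ch.atom.is_cap_hydrogen
            assert ch.atom.partial_charge == 0.0

    def test_proline_cap_saturated_like_amide(self):
        s = make_toy_complex(ToySpec(
            n_residues=5, sequence=("ALA", "ALA", "PRO", "ALA", "ALA"),
            seed=6, n_waters=0))
        # PRO(3) is cap_next of residue 2: removing R_2 in the caps-only
        # systems puts a saturating H on the proline ring nitrogen
        capped = build_caps(s, ResidueId("A", 2))
        systems = build_fragment_systems(capped, toy_ligand_id(), s)
        cc = systems["CC"]
        inner = [a for a, rn in zip(cc.atoms, cc.residue_names)
                 if rn == "CAP" and a.name == "HNC"]
        assert inner, "expected an inner saturating H on the proline N"
        pro_n = s.get(ResidueId("A", 3)).get_atom("N").position
        d = min(np.linalg.norm(a.position - pro_n) for a in inner)
        assert d == pytest.approx(1.01, abs=1e-3)

    def test_broken_chain_detected(self, pentamer):
        broken = pentamer.copy()
        for res in broken.protein_residues[3:]:
            for a in res.atoms:
                a.position = a.position + np.array([50.0, 0.0, 0.0])
        with pytest.raises(ChainDiscontinuityError):
            build_caps(broken, ResidueId("A", 3))


def _water(seq, pos):
    return Residue("W", seq, "HOH", [Atom("O", "O", np.asarray(pos, float))],
                   Role.WATER)


class TestAssignWaters:
    def test_nearest_residue_priority(self):
        # water O at 2.8 A from residue A's carbonyl O, 3.2 A from B's N
        res_a = Residue("A", 1, "GLY", [Atom("O", "O", (0.0, 0.0, 0.0)),
                                        Atom("CA", "C", (0.0, 1.5, 0.0))],
                        Role.PROTEIN)
        res_b = Residue("A", 2, "GLY", [Atom("N", "N", (6.0, 0.0, 0.0)),
                                        Atom("CA", "C", (6.0, 1.5, 0.0))],
                        Role.PROTEIN)
        s = Structure([res_a, res_b, _water(301, (2.8, 0.0, 0.0))])
        out = assign_waters(s, [res_a.id, res_b.id], hbond_dmax=3.5)
        assert out[ResidueId("W", 301)] == res_a.id
        assert out.unassigned == []

    def test_beyond_cutoff_unassigned(self):
        res = Residue("A", 1, "GLY", [Atom("O", "O", (0.0, 0.0, 0.0))],
                      Role.PROTEIN)
        s = Structure([res, _water(301, (4.2, 0.0, 0.0))])
        out = assign_waters(s, [res.id], hbond_dmax=3.5)
        assert out.assigned == {}
        assert out.unassigned == [ResidueId("W", 301)]

    def test_matches_exhaustive_search_randomised(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            residues = []
            for i in range(1, 4):
                atoms = [Atom("N", "N", rng.uniform(-4, 4, 3)),
                         Atom("O", "O", rng.uniform(-4, 4, 3)),
                         Atom("CB", "C", rng.uniform(-4, 4, 3))]
                residues.append(Residue("A", i, "GLY", atoms, Role.PROTEIN))
            waters = [_water(301 + k, rng.uniform(-6, 6, 3)) for k in range(3)]
            s = Structure(residues + waters)
            out = assign_waters(s, [r.id for r in residues], hbond_dmax=3.5)
            # brute force over every water-residue pair, N/O atoms only
            for w in waters:
                oxy = w.atoms[0].position
                best = None
                for res in residues:
                    d = min(np.linalg.norm(a.position - oxy)
                            for a in res.atoms if a.element in ("N", "O"))
                    if d <= 3.5 and (best is None or d < best[0]):
                        best = (d, res.id)
                if best is None:
                    assert w.id in out.unassigned
                else:
                    assert out[w.id] == best[1]

    def test_each_water_assigned_at_most_once(self, toy_structure):
        pocket = [r.id for r in toy_structure.protein_residues]
        out = assign_waters(toy_structure, pocket)
        all_attached = [w for rid in pocket for w in out.waters_of(rid)]
        assert len(all_attached) == len(set(all_attached))


@pytest.fixture(scope="module")
def systems_mid(pentamer):
    capped = build_caps(pentamer, ResidueId("A", 3))
    return build_fragment_systems(capped, toy_ligand_id(), pentamer), pentamer


class TestFragmentSystems:
    def test_term_membership(self, systems_mid):
        systems, _ = systems_mid
        assert "LIG" in systems["L_CRC"].residue_names
        assert "LIG" in systems["L_CC"].residue_names
        assert "LIG" not in systems["CRC"].residue_names
        assert "LIG" not in systems["CC"].residue_names
        assert "ASP" in systems["L_CRC"].residue_names
        assert "ASP" not in systems["L_CC"].residue_names

    def test_charge_bookkeeping_charged_residue(self, systems_mid):
        systems, _ = systems_mid  # R_3 = ASP (-1), neutral ligand and caps
        assert systems["L_CRC"].net_charge == -1
        assert systems["CRC"].net_charge == -1
        assert systems["L_CC"].net_charge == 0
        assert systems["CC"].net_charge == 0

    def test_charge_bookkeeping_neutral(self):
        s = make_toy_complex(ToySpec(
            n_residues=5, sequence=("ALA",) * 5, seed=1, n_waters=0))
        capped = build_caps(s, ResidueId("A", 3))
        systems = build_fragment_systems(capped, toy_ligand_id(), s)
        assert all(sys_.net_charge == 0 for sys_ in systems.values())

    def test_atom_count_identity(self, toy_structure, ligand_id):
        # |L_CRC| - |L_CC| == |CRC| - |CC| for every residue
        from mfccpocket.mfcc_fragmentation import assign_waters as aw

        pocket = [r.id for r in toy_structure.protein_residues]
        wmap = aw(toy_structure, pocket)
        for rid in pocket:
            capped = build_caps(toy_structure, rid)
            capped.attached_waters = wmap.waters_of(rid)
            systems = build_fragment_systems(capped, ligand_id, toy_structure)
            lhs = len(systems["L_CRC"].atoms) - len(systems["L_CC"].atoms)
            rhs = len(systems["CRC"].atoms) - len(systems["CC"].atoms)
            assert lhs == rhs

    def test_waters_travel_with_residue(self, toy_structure, ligand_id):
        pocket = [r.id for r in toy_structure.protein_residues]
        wmap = assign_waters(toy_structure, pocket)
        rid = next(r for r in pocket if wmap.waters_of(r))
        capped = build_caps(toy_structure, rid)
        capped.attached_waters = wmap.waters_of(rid)
        systems = build_fragment_systems(capped, ligand_id, toy_structure)
        assert "HOH" in systems["L_CRC"].residue_names
        assert "HOH" in systems["CRC"].residue_names
        assert "HOH" not in systems["L_CC"].residue_names
        assert "HOH" not in systems["CC"].residue_names

    def test_no_duplicated_atoms_within_a_term(self, systems_mid):
        systems, _ = systems_mid
        for sys_ in systems.values():
            seen = {id(a) for a in sys_.atoms}
            assert len(seen) == len(sys_.atoms)
            coords = np.array([a.position for a in sys_.atoms])
            from scipy.spatial.distance import pdist

            assert pdist(coords).min() > 0.0
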