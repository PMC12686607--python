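"""Structure model: PDB round trips, altloc policies, roles, protonation."""
import numpy as np
import pytest

from mfccpocket.errors import (
    ContentError, MfccError, PDBParseError, UnparameterizedResidueError,
)
from mfccpocket.mfcc_fragmentation import FragmentSystem
from mfccpocket.structure_model import (
    Atom, Residue, ResidueId, Role, Structure, assign_protonation, read_pdb,
    read_xyz, total_formal_charge, write_fragment_xyz, write_pdb,
)
from mfccpocket.synthetic_data import ToySpec, make_toy_complex


def _pdb_line(record, serial, name, resname, chain, seq, xyz, occ=1.0,
              altloc=" ", element="C"):
    x, y, z = xyz
    padded = f" {name:<3s}" if len(element) == 1 and len(name) < 4 else f"{name:<4s}"
    return (f"{record:<6s}{serial:5d} {padded}{altloc}{resname:<3s} {chain}"
            f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


@pytest.fixture
def tiny_pdb(tmp_path):
    """3-residue peptide + ligand + 2 waters + Zn ion, with one altloc pair."""
    lines = []
    serial = 1
    for i, resname in enumerate(("ALA", "GLY", "ALA"), start=1):
        for name, dx in (("N", 0.0), ("CA", 1.4), ("C", 2.4), ("O", 3.0)):
            el = name[0]
            lines.append(_pdb_line("ATOM", serial, name, resname, "A", i,
                                   (i * 4.0 + dx, 0.0, 0.0), element=el))
            serial += 1
    # altloc pair on the first residue CB
    lines.append(_pdb_line("ATOM", serial, "CB", "ALA", "A", 1,
                           (4.1, 1.5, 0.0), occ=0.6, altloc="A"))
    serial += 1
    lines.append(_pdb_line("ATOM", serial, "CB", "ALA", "A", 1,
                           (4.1, -1.5, 0.0), occ=0.4, altloc="B"))
    serial += 1
    lines.append(f"TER   {serial:5d}")
    serial += 1
    for k, (name, el, pos) in enumerate(
            [("C1", "C", (0.0, 5.0, 0.0)), ("O1", "O", (1.2, 5.0, 0.0))]):
        lines.append(_pdb_line("HETATM", serial, name, "LIG", "L", 201,
                               pos, element=el))
        serial += 1
    for k in range(2):
        lines.append(_pdb_line("HETATM", serial, "O", "HOH", "W", 301 + k,
                               (8.0 + k, 8.0, 0.0), element="O"))
        serial += 1
    lines.append(_pdb_line("HETATM", serial, "ZN", "ZN", "Z", 401,
                           (9.0, 9.0, 9.0), element="ZN"))
    lines.append("END")
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPdb:
    def test_roles_and_counts(self, tiny_pdb):
        s = read_pdb(tiny_pdb)
        assert len(s.protein_residues) == 3
        assert len(s.ligands) == 1
        assert len(s.waters) == 2
        assert [r.role for r in s.residues].count(Role.ION) == 1

    def test_ion_role_and_charge(self, tiny_pdb):
        s = read_pdb(tiny_pdb)
        zn = s.get(ResidueId("Z", 401))
        assert zn.role == Role.ION
        assert zn.formal_charge == 2

    def test_altloc_highest_occupancy(self, tiny_pdb):
        s = read_pdb(tiny_pdb, altloc_policy="highest_occupancy")
        cb = s.get(ResidueId("A", 1)).get_atom("CB")
        assert cb.position[1] == pytest.approx(1.5)  # conformer A (occ 0.6)

    def test_altloc_label_a(self, tiny_pdb):
        s = read_pdb(tiny_pdb, altloc_policy="label_A")
        cb = s.get(ResidueId("A", 1)).get_atom("CB")
        assert cb.position[1] == pytest.approx(1.5)

    def test_altloc_resolution_unique_names(self, tiny_pdb):
        s = read_pdb(tiny_pdb)
        for res in s.residues:
            names = [a.name for a in res.atoms]
            assert len(names) == len(set(names))

    def test_malformed_coordinate_reports_line(self, tiny_pdb, tmp_path):
        text = tiny_pdb.read_text().splitlines()
        text[2] = text[2][:32] + "xxxxxx" + text[2][38:]
        bad = tmp_path / "bad.pdb"
        bad.write_text("\n".join(text))
        with pytest.raises(PDBParseError) as err:
            read_pdb(bad)
        assert err.value.line_number == 3

    def test_no_protein_is_content_error(self, tmp_path):
        path = tmp_path / "lig_only.pdb"
        path.write_text(_pdb_line("HETATM", 1, "C1", "LIG", "L", 1,
                                  (0, 0, 0)) + "\nEND\n")
        with pytest.raises(ContentError):
            read_pdb(path)


class TestRoundTrip:
    def test_write_read_preserves_model(self, tmp_path):
        s = make_toy_complex(ToySpec(seed=5))
        path = tmp_path / "toy.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert [r.id for r in back.residues] == [r.id for r in s.residues]
        assert [r.role for r in back.residues] == [r.role for r in s.residues]
        for orig, re_read in zip(s.residues, back.residues):
            assert [a.name for a in re_read.atoms] == [a.name for a in orig.atoms]
            np.testing.assert_allclose(
                re_read.coords(), orig.coords(), atol=1e-3)


@pytest.fixture(scope="module")
def protonated():
    return make_toy_complex(ToySpec(seed=4))  # ASP at 3, LYS at 7


class TestProtonation:
    def test_asp_deprotonated(self, protonated):
        asp = protonated.get(ResidueId("A", 3))
        assert asp.name == "ASP"
        assert asp.formal_charge == -1
        assert asp.get_atom("HD2") is None
        assert asp.get_atom("OD2") is not None

    def test_lys_protonated(self, protonated):
        lys = protonated.get(ResidueId("A", 7))
        assert lys.name == "LYS"
        assert lys.formal_charge == 1
        nz_h = [a for a in lys.atoms if a.name.startswith("HZ")]
        assert len(nz_h) == 3

    def test_added_hydrogens_flagged(self, protonated):
        for res in protonated.protein_residues:
            for atom in res.atoms:
                assert atom.is_added_hydrogen == (atom.element == "H")

    def test_formal_charge_sum(self, protonated):
        # zwitterionic termini cancel, leaving (LYS+ARG) - (ASP+GLU)
        n_basic = sum(r.name in ("LYS", "ARG") for r in protonated.protein_residues)
        n_acid = sum(r.name in ("ASP", "GLU") for r in protonated.protein_residues)
        assert total_formal_charge(protonated) == n_basic - n_acid

    def test_his_protonated_override(self):
        s = make_toy_complex(ToySpec(
            n_residues=5, sequence=("ALA", "HIS", "ALA", "ALA", "ALA"),
            seed=2, n_waters=0))
        assign_protonation(s, his_states={ResidueId("A", 2): "HIP"})
        his = s.get(ResidueId("A", 2))
        assert his.formal_charge == 1
        assert his.get_atom("HD1") is not None
        assert his.get_atom("HE2") is not None

    def test_his_default_neutral_ne_tautomer(self):
        s = make_toy_complex(ToySpec(
            n_residues=5, sequence=("ALA", "HIS", "ALA", "ALA", "ALA"),
            seed=2, n_waters=0))
        his = s.get(ResidueId("A", 2))
        assert his.formal_charge == 0
        assert his.get_atom("HE2") is not None
        assert his.get_atom("HD1") is None

    def test_water_gets_two_hydrogens(self, protonated):
        for w in protonated.waters:
            assert sum(a.element == "H" for a in w.atoms) == 2
            assert sum(a.element == "O" for a in w.atoms) == 1

    def test_unknown_residue_errors(self):
        res = Residue("A", 1, "XYZ", [
            Atom("N", "N", (0, 0, 0)), Atom("CA", "C", (1.4, 0, 0)),
            Atom("C", "C", (2.0, 1.0, 0)), Atom("O", "O", (3.0, 1.0, 0)),
        ], Role.PROTEIN)
        s = Structure([res])
        with pytest.raises(UnparameterizedResidueError):
            assign_protonation(s)

    def test_missing_side_chain_rejected_without_hook(self):
        res = Residue("A", 1, "ALA", [  # CB missing
            Atom("N", "N", (0, 0, 0)), Atom("CA", "C", (1.4, 0, 0)),
            Atom("C", "C", (2.0, 1.0, 0)), Atom("O", "O", (3.0, 1.0, 0)),
        ], Role.PROTEIN)
        with pytest.raises(UnparameterizedResidueError, match="CB"):
            assign_protonation(Structure([res]))


class TestXyz:
    def _system(self, n):
        atoms = [Atom(f"C{i}", "C", (float(i), 0.5, -0.25)) for i in range(n)]
        return FragmentSystem(term="CC", atoms=atoms, net_charge=0,
                              residue_names=["X"] * n)

    def test_header_and_count(self, tmp_path):
        path = tmp_path / "frag.xyz"
        write_fragment_xyz(self._system(5), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "5"
        assert "CC" in lines[1] and "charge=0" in lines[1]
        assert len(lines) == 7

    def test_empty_system_errors(self, tmp_path):
        path = tmp_path / "empty.xyz"
        with pytest.raises(MfccError):
            write_fragment_xyz(self._system(0), path)
        assert not path.exists()

    def test_round_trip_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        atoms = [Atom(f"O{i}", "O", rng.normal(size=3) * 10) for i in range(6)]
        system = FragmentSystem(term="CRC", atoms=atoms,
                                residue_names=["X"] * 6)
        path = tmp_path / "frag.xyz"
        write_fragment_xyz(system, path)
        back = read_xyz(path)
        np.testing.assert_allclose(
            np.array([a.position for a in back]),
            np.array([a.position for a in atoms]), atol=1e-6)
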