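import json

import numpy as np
import pytest

from mqsar.structures import (
    Atom,
    Molecule,
    ParseError,
    ResidueSet,
    read_energy_table,
    read_structure,
    select_active_site,
    write_xyz,
)


class TestXYZ:
    def test_water_roundtrip_preserves_elements_and_coords(self, water, tmp_path):
        p = tmp_path / "w.xyz"
        write_xyz(water, p)
        back = read_structure(p)
        assert back.elements == ["O", "H", "H"]
        assert np.allclose(back.coords, water.coords, atol=1e-4)

    def test_atom_count_mismatch_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("5\nwater\nO 0 0 0\nH 1 0 0\nH 0 1 0\nH 0 0 1\n")
        with pytest.raises(ParseError, match="5 atoms"):
            read_structure(p)

    def test_unknown_element_rejected(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\nx\nQq 0 0 0\n")
        with pytest.raises(ParseError, match="element"):
            read_structure(p)


class TestPDB:
    def _pdb(self, tmp_path):
        lines = [
            "ATOM      1  N   LYS A  58      10.000   0.000   0.000  1.00  0.00           N",
            "ATOM      2  CA  LYS A  58      11.000   0.500   0.000  1.00  0.00           C",
            "ATOM      3  N   ASP A  54       2.000   1.000   0.000  1.00  0.00           N",
            "ATOM      4  CA  ASP A  54       3.000   1.500   0.000  1.00  0.00           C",
            "HETATM    5  C1  LIG A 200       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    6  O1  LIG A 200       1.200   0.000   0.000  1.00  0.00           O",
            "END",
        ]
        p = tmp_path / "cpx.pdb"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_two_residues_and_hetatm_ligand(self, tmp_path):
        residues, ligand = read_structure(self._pdb(tmp_path))
        assert len(residues) == 2
        assert sorted(residues.names()) == ["ASP54", "LYS58"]
        assert ligand is not None and len(ligand) == 2

    def test_active_site_from_pdb(self, tmp_path):
        residues, ligand = read_structure(self._pdb(tmp_path))
        site = select_active_site(residues, ligand, radius=5.0)
        # ASP54 nearest atom is ~2.06 A from the ligand; LYS58 is ~8.8 A away
        assert site.names() == ["ASP54"]


class TestSDF:
    def test_v2000_molecule_with_bonds(self, tmp_path):
        block = (
            "methanol\n  test\n\n"
            "  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "    1.4000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0\n"
            "  1  2  1  0\n"
            "M  END\n$$$$\n"
        )
        p = tmp_path / "m.sdf"
        p.write_text(block)
        mols = read_structure(p)
        assert len(mols) == 1
        assert mols[0].elements == ["C", "O"]
        assert mols[0].bonds == [(0, 1)]
        assert mols[0].name == "methanol"


class TestActiveSite:
    def _residue(self, name, offset):
        return Molecule(
            name,
            [Atom("N", np.array(offset)), Atom("O", np.array(offset) + [1.0, 0, 0])],
            role="residue",
        )

    def test_boundary_inclusion_at_radius(self, water):
        near = self._residue("near", [0.0, 0.0, 4.9])
        far = self._residue("far", [0.0, 0.0, 5.2])
        site = select_active_site(ResidueSet([near, far]), water, radius=5.0)
        assert site.names() == ["near"]

    def test_whole_residue_never_fragmented(self, water):
        # one atom inside, one far outside: the whole residue is kept intact
        res = Molecule(
            "straddle",
            [Atom("N", [0.0, 0.0, 3.0]), Atom("O", [0.0, 0.0, 30.0])],
            role="residue",
        )
        site = select_active_site(ResidueSet([res]), water, radius=5.0)
        assert len(site["straddle"]) == 2

    def test_matches_brute_force_on_synthetic_pocket(self):
        from mqsar.synthetic import gen_ligand_series, gen_pocket

        lig = gen_ligand_series(3, 1)[0][0]
        pocket = gen_pocket(3, 10)
        site = select_active_site(pocket, lig, radius=5.0)
        expected = set()
        for res in pocket.residues:  # brute-force all-pairs distance check
            for ra in res.atoms:
                for la in lig.atoms:
                    if np.linalg.norm(ra.coords - la.coords) <= 5.0:
                        expected.add(res.name)
        assert set(site.names()) == expected
        assert 0 < len(expected) < len(pocket)

    def test_invariant_under_joint_rigid_translation(self, water):
        res = self._residue("r1", [0.0, 0.0, 4.0])
        t = np.array([12.3, -4.5, 6.7])
        I = np.eye(3)
        site0 = select_active_site(ResidueSet([res]), water, radius=5.0)
        site1 = select_active_site(
            ResidueSet([res.transformed(I, t)]), water.transformed(I, t), radius=5.0
        )
        assert site0.names() == site1.names()

    def test_empty_radius_and_ligand_errors(self, water):
        with pytest.raises(ValueError):
            select_active_site(ResidueSet([]), water, radius=-1.0)


class TestEnergyTable:
    def test_csv_and_json_forms_agree(self, tmp_path):
        csv = tmp_path / "e.csv"
        csv.write_text("system_id,energy\na,-1.5\nb,2.0\nc,0.25\n")
        js = tmp_path / "e.json"
        js.write_text(json.dumps([{"system_id": k, "energy": v} for k, v in
                                  [("a", -1.5), ("b", 2.0), ("c", 0.25)]]))
        t1, t2 = read_energy_table(csv), read_energy_table(js)
        assert len(t1) == 3
        assert t1.energies == t2.energies

    def test_duplicate_system_id_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("system_id,energy\na,1\na,2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_energy_table(p)

    def test_missing_column_and_non_numeric(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("system_id,value\na,1\n")
        with pytest.raises(ParseError, match="energy"):
            read_energy_table(p)
        p.write_text("system_id,energy\na,oops\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_energy_table(p)

    def test_decimal_commas_normalised(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text('system_id,energy\na,"-17,3721"\n')
        assert read_energy_table(p)["a"] == pytest.approx(-17.3721)


class TestPerceiveBonds:
    def test_water_connectivity_recovered(self, water):
        from mqsar.structures import perceive_bonds

        bare = Molecule("w", [Atom(a.element, a.coords.copy(), atom_id=a.atom_id) for a in water.atoms])
        assert not bare.bonds
        out = perceive_bonds(bare)
        assert set(out.bonds) == {(0, 1), (0, 2)}

    def test_distant_atoms_not_bonded(self):
        from mqsar.structures import perceive_bonds

        mol = Molecule("x", [Atom("C", [0, 0, 0], atom_id=0), Atom("C", [5, 0, 0], atom_id=1)])
        assert perceive_bonds(mol).bonds == []


class TestMoleculeInvariants:
    def test_self_bond_rejected(self):
        with pytest.raises(ValueError, match="self-bond"):
            Molecule("x", [Atom("C", [0, 0, 0], atom_id=0)], bonds=[(0, 0)])

    def test_bond_to_missing_atom_rejected(self):
        with pytest.raises(ValueError, match="missing atom"):
            Molecule("x", [Atom("C", [0, 0, 0], atom_id=0)], bonds=[(0, 3)])

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError, match="no atoms"):
            Molecule("x", [])
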