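"""Selection grammar, point mutation and crystal-water filtering."""

import numpy as np
import pytest

from mdpost.prep import filter_crystal_waters, mutate_residue
from mdpost.selection import SelectionError, select
from mdpost.structure import Structure

from .conftest import make_atom, make_ca_chain, make_ideal_asp


@pytest.fixture
def protein_with_ligand() -> Structure:
    atoms = list(make_ca_chain(30, start_resid=160).atoms)  # resids 160..189
    base = len(atoms)
    for k, name in enumerate(("P", "O1P", "O2P", "O3P")):
        atoms.append(
            make_atom(base + k + 1, name, "P" if name == "P" else "O", 300, "PTR", "A",
                      (20.0 + k, 0.0, 0.0))
        )
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure(atoms)


class TestSelect:
    def test_name_ca_on_ten_residue_chain(self):
        s = make_ca_chain(10)
        assert select(s, "name CA").size == 10

    def test_resid_range_and_name(self, protein_with_ligand):
        idx = select(protein_with_ligand, "resid 160-185 and name CA")
        assert idx.size == 26

    def test_resname_selects_exactly_the_ligand(self, protein_with_ligand):
        idx = select(protein_with_ligand, "resname PTR")
        assert [protein_with_ligand.atoms[i].residue_name for i in idx] == ["PTR"] * 4

    def test_uppercase_boolean_keywords(self, protein_with_ligand):
        a = select(protein_with_ligand, "resid 160-185 AND name CA")
        b = select(protein_with_ligand, "resid 160-185 and name CA")
        np.testing.assert_array_equal(a, b)

    def test_set_algebra_and_idempotence(self, protein_with_ligand):
        s = protein_with_ligand
        both = set(select(s, "resid 160-170 and name CA"))
        outer = set(select(s, "name CA"))
        assert both <= outer
        np.testing.assert_array_equal(select(s, "name CA"), select(s, "name CA"))
        not_ca = set(select(s, "not name CA"))
        assert not_ca.isdisjoint(outer)
        assert not_ca | outer == set(range(s.n_atoms))

    def test_bad_expression_raises(self, protein_with_ligand):
        with pytest.raises(SelectionError):
            select(protein_with_ligand, "resid !! garbage")
        with pytest.raises(SelectionError):
            select(protein_with_ligand, "")


class TestMutateResidue:
    def test_asp_to_ala_truncates_and_completes_methyl(self):
        s = make_ideal_asp()
        out = mutate_residue(s, ("A", 181), "ALA")
        names = {a.name for a in out}
        assert names == {"N", "CA", "C", "O", "CB", "HB1", "HB2", "HB3"}
        assert all(a.residue_name == "ALA" for a in out)
        # backbone untouched
        for nm in ("N", "CA", "C", "O", "CB"):
            i_old = [a.name for a in s].index(nm)
            i_new = [a.name for a in out].index(nm)
            np.testing.assert_allclose(out.atoms[i_new].position, s.atoms[i_old].position)
        # methyl hydrogens at ideal C-H length
        cb = out.coords[[a.name for a in out].index("CB")]
        for nm in ("HB1", "HB2", "HB3"):
            h = out.coords[[a.name for a in out].index(nm)]
            assert np.linalg.norm(h - cb) == pytest.approx(1.09, abs=1e-6)

    def test_asp_to_glu_grafts_ideal_carboxylate(self):
        s = make_ideal_asp()
        out = mutate_residue(s, ("A", 181), "GLU")
        pos = {a.name: a.position for a in out}
        assert {"CB", "CG", "CD", "OE1", "OE2"} <= set(pos)
        assert np.linalg.norm(pos["CG"] - pos["CB"]) == pytest.approx(1.52, abs=0.02)
        assert np.linalg.norm(pos["CD"] - pos["CG"]) == pytest.approx(1.52, abs=0.02)
        assert np.linalg.norm(pos["OE1"] - pos["CD"]) == pytest.approx(1.25, abs=0.02)
        assert np.linalg.norm(pos["OE2"] - pos["CD"]) == pytest.approx(1.25, abs=0.02)
        assert all(a.residue_name == "GLU" for a in out)

    def test_non_asp_source_rejected(self):
        s = make_ca_chain(3)  # glycines
        with pytest.raises(ValueError, match="ASP"):
            mutate_residue(s, ("A", 1), "ALA")

    def test_unsupported_target_rejected(self):
        s = make_ideal_asp()
        with pytest.raises(ValueError, match="unsupported"):
            mutate_residue(s, ("A", 181), "TRP")

    def test_missing_backbone_rejected(self):
        s = make_ideal_asp()
        no_ca = s.subset([i for i, a in enumerate(s.atoms) if a.name != "CA"])
        with pytest.raises(ValueError, match="backbone"):
            mutate_residue(no_ca, ("A", 181), "ALA")


class TestFilterCrystalWaters:
    def _with_waters(self, distances) -> Structure:
        atoms = [make_atom(1, "P", "P", 1, "PTR", "A", (0.0, 0.0, 0.0))]
        for k, d in enumerate(distances):
            atoms.append(
                make_atom(k + 2, "O", "O", 100 + k, "HOH", "W", (d, 0.0, 0.0))
            )
        return Structure(atoms)

    def test_boundary_inside_kept(self):
        s = self._with_waters([3.9])
        out = filter_crystal_waters(s, [0], cutoff=4.0)
        assert out.n_atoms == 2

    def test_boundary_outside_removed(self):
        s = self._with_waters([4.1])
        out = filter_crystal_waters(s, [0], cutoff=4.0)
        assert out.n_atoms == 1
        assert out.atoms[0].residue_name == "PTR"

    def test_no_waters_is_identity(self):
        s = Structure([make_atom(1, "P", "P", 1, "PTR", "A", (0, 0, 0)),
                       make_atom(2, "CA", "C", 2, "GLY", "A", (9, 0, 0))])
        out = filter_crystal_waters(s, [0], cutoff=4.0)
        assert [a.name for a in out] == ["P", "CA"]

    def test_non_water_atoms_never_touched(self):
        s = self._with_waters([2.0, 8.0])
        out = filter_crystal_waters(s, [0], cutoff=4.0)
        kept_names = [(a.residue_name, a.residue_number) for a in out]
        assert ("PTR", 1) in kept_names and ("HOH", 100) in kept_names
        assert ("HOH", 101) not in kept_names

    def test_empty_ligand_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_crystal_waters(self._with_waters([3.0]), [], cutoff=4.0)
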