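"""Pairwise Coulomb/LJ energies and the per-residue decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdpost.constants import K_COULOMB
from mdpost.energy import (
    coulomb_energy,
    lennard_jones_energy,
    per_residue_decomposition,
)
from mdpost.structure import Structure, Trajectory
from mdpost.synthetic import generate_toy_complex

from .conftest import make_atom


def _pair(r, q1=1.0, q2=1.0, sigma=3.0, eps=0.1):
    a = Structure([make_atom(1, "A", "C", 1, "AAA", "A", (0, 0, 0),
                             charge=q1, lj_sigma=sigma, lj_epsilon=eps)])
    b = Structure([make_atom(2, "B", "C", 2, "BBB", "B", (r, 0, 0),
                             charge=q2, lj_sigma=sigma, lj_epsilon=eps)])
    return a, b


def brute_force_energies(group_a: Structure, group_b: Structure) -> tuple[float, float]:
    """Independent pair-loop oracle (scalar arithmetic only)."""
    ele = vdw = 0.0
    for x in group_a.atoms:
        for y in group_b.atoms:
            r = float(np.linalg.norm(x.position - y.position))
            ele += K_COULOMB * x.charge * y.charge / r
            sigma = 0.5 * (x.lj_sigma + y.lj_sigma)
            eps = (x.lj_epsilon * y.lj_epsilon) ** 0.5
            vdw += 4.0 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)
    return ele, vdw


class TestCoulomb:
    def test_hand_value_100_kcal(self):
        a, b = _pair(3.320637)
        assert coulomb_energy(a, b) == pytest.approx(100.0, rel=1e-9)

    def test_zero_charge_gives_zero(self):
        a, b = _pair(3.0, q1=0.0)
        assert coulomb_energy(a, b) == 0.0

    def test_one_over_r_scaling(self):
        a1, b1 = _pair(2.5)
        a2, b2 = _pair(5.0)
        assert coulomb_energy(a1, b1) == pytest.approx(2.0 * coulomb_energy(a2, b2))

    def test_overlapping_atoms_rejected(self):
        a, b = _pair(1e-9)
        with pytest.raises(ValueError, match="overlap"):
            coulomb_energy(a, b)


class TestLennardJones:
    def test_minimum_at_two_to_the_sixth_sigma(self):
        a, b = _pair(2.0 ** (1 / 6) * 3.0, eps=0.25)
        assert lennard_jones_energy(a, b) == pytest.approx(-0.25, rel=1e-12)

    def test_vanishes_at_long_range(self):
        a, b = _pair(500.0)
        assert abs(lennard_jones_energy(a, b)) < 1e-12

    def test_matches_brute_force_on_toy_groups(self):
        c = generate_toy_complex(3, 2, seed=8)
        rec = c.subset(range(3))
        lig = c.subset(range(3, 5))
        ele_o, vdw_o = brute_force_energies(rec, lig)
        assert coulomb_energy(rec, lig) == pytest.approx(ele_o, rel=1e-12)
        assert lennard_jones_energy(rec, lig) == pytest.approx(vdw_o, rel=1e-12)

    def test_symmetric_in_group_order(self, toy_complex):
        rec = toy_complex.subset(range(9))
        lig = toy_complex.subset(range(9, 12))
        assert coulomb_energy(rec, lig) == pytest.approx(coulomb_energy(lig, rec))
        assert lennard_jones_energy(rec, lig) == pytest.approx(
            lennard_jones_energy(lig, rec)
        )


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_brute_force_equivalence_on_random_complexes(seed):
    """Vectorised energies equal the scalar pair loop on any toy complex."""
    c = generate_toy_complex(8, 4, seed=seed)
    rec, lig = c.subset(range(8)), c.subset(range(8, 12))
    ele_o, vdw_o = brute_force_energies(rec, lig)
    assert coulomb_energy(rec, lig) == pytest.approx(ele_o, rel=1e-10)
    assert lennard_jones_energy(rec, lig) == pytest.approx(vdw_o, rel=1e-10)


class TestPerResidueDecomposition:
    def test_single_frame_matches_direct_evaluation(self, toy_complex):
        lig_idx = np.arange(9, 12)
        traj = Trajectory(toy_complex.coords[None], 10.0, toy_complex)
        table = per_residue_decomposition(traj, lig_idx)
        lig = toy_complex.subset(lig_idx)
        for key, idx in toy_complex.residue_index.items():
            if toy_complex.atoms[idx[0]].residue_name == "LIG":
                continue
            label = f"REC{key[1]}"
            res = toy_complex.subset(idx)
            assert table.loc[label, "elec_kcal_mol"] == pytest.approx(
                coulomb_energy(lig, res), rel=1e-10
            )
            assert table.loc[label, "vdw_kcal_mol"] == pytest.approx(
                lennard_jones_energy(lig, res), rel=1e-10
            )

    def test_additivity_every_frame(self):
        c = generate_toy_complex(30, 6, seed=13, box=12.0)
        lig_idx = np.arange(30, 36)
        rng = np.random.default_rng(0)
        coords = c.coords[None] + 0.05 * rng.standard_normal((4, 36, 3))
        traj = Trajectory(coords, 10.0, c)
        table = per_residue_decomposition(traj, lig_idx)
        whole = np.zeros(4)
        for f in range(4):
            frame = c.with_coords(coords[f])
            rec = frame.subset(range(30))
            lig = frame.subset(lig_idx)
            whole[f] = coulomb_energy(rec, lig) + lennard_jones_energy(rec, lig)
        assert table["total_kcal_mol"].sum() == pytest.approx(whole.mean(), rel=1e-12)

    def test_zero_parameter_residue_contributes_nothing(self):
        atoms = [
            make_atom(1, "C1", "C", 1, "REC", "A", (0, 0, 0), charge=0.0, lj_epsilon=0.0),
            make_atom(2, "L1", "C", 2, "LIG", "B", (4, 0, 0), charge=1.0, lj_sigma=3.0,
                      lj_epsilon=0.1),
        ]
        s = Structure(atoms)
        traj = Trajectory(s.coords[None], 10.0, s)
        table = per_residue_decomposition(traj, [1])
        assert table.loc["REC1"].tolist() == [0.0] * 6

    def test_replicated_frames_leave_means_unchanged(self, toy_complex):
        lig_idx = np.arange(9, 12)
        one = Trajectory(toy_complex.coords[None], 10.0, toy_complex)
        two = Trajectory(np.repeat(toy_complex.coords[None], 2, axis=0), 10.0, toy_complex)
        a = per_residue_decomposition(one, lig_idx)
        b = per_residue_decomposition(two, lig_idx)
        np.testing.assert_allclose(
            a["total_kcal_mol"].to_numpy(), b["total_kcal_mol"].to_numpy(), rtol=1e-12
        )

    def test_ligand_overlapping_panel_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="overlap"):
            per_residue_decomposition(
                Trajectory(toy_complex.coords[None], 10.0, toy_complex),
                [9, 10, 11],
                residue_list=[("B", 1000, "")],
            )
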