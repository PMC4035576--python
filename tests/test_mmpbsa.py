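"""MM-PBSA assembly and the single-trajectory protocol."""

import numpy as np
import pytest

from mdpost.energy import coulomb_energy, lennard_jones_energy
from mdpost.minimize import HarmonicBond, ToyPotential
from mdpost.mmpbsa import (
    BindingFreeEnergy,
    assemble_binding_free_energy,
    mmpbsa_single_trajectory,
)
from mdpost.pb import polar_binding_component
from mdpost.solvation import SolvationParameters, nonpolar_solvation, shrake_rupley_sasa
from mdpost.structure import Structure, Trajectory

from .conftest import make_atom


class TestAssembly:
    def test_sum_of_five_terms(self):
        result = assemble_binding_free_energy(
            dict(
                delta_E_ele=-100.0,
                delta_E_vdw=-20.0,
                delta_G_pol=90.0,
                delta_G_nonpol=-3.0,
                minus_T_delta_S=21.0,
            )
        )
        assert result.delta_G_bind == pytest.approx(-12.0)
        assert result.delta_E_MM == pytest.approx(-120.0)
        assert result.delta_G_sol == pytest.approx(87.0)

    def test_sequence_form_accepted(self):
        result = assemble_binding_free_energy([-1.0, -2.0, 3.0, -0.5, 0.25])
        assert result.delta_G_bind == pytest.approx(-0.25)

    def test_all_zero_components(self):
        assert assemble_binding_free_energy([0.0] * 5).delta_G_bind == 0.0

    def test_missing_term_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_binding_free_energy(dict(delta_E_ele=-1.0))
        with pytest.raises(ValueError, match="5 components"):
            assemble_binding_free_energy([1.0, 2.0])

    def test_non_finite_term_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            assemble_binding_free_energy([np.nan, 0.0, 0.0, 0.0, 0.0])

    def test_additivity_invariant_exact(self):
        bfe = BindingFreeEnergy(-321.3, -25.7, 290.5, -3.6, 21.4)
        total = (
            bfe.delta_E_ele
            + bfe.delta_E_vdw
            + bfe.delta_G_pol
            + bfe.delta_G_nonpol
            + bfe.minus_T_delta_S
        )
        assert bfe.delta_G_bind == pytest.approx(total, abs=1e-9)


def _bound_complex() -> Structure:
    """Two-atom receptor + one-atom ligand, charged, in contact."""
    return Structure(
        [
            make_atom(1, "Q1", "X", 1, "REC", "A", (0.0, 0.0, 0.0), charge=0.5,
                      lj_sigma=3.0, lj_epsilon=0.1, radius=1.8, mass=12.0),
            make_atom(2, "Q2", "X", 2, "REC", "A", (3.0, 0.0, 0.0), charge=0.5,
                      lj_sigma=3.0, lj_epsilon=0.1, radius=1.8, mass=12.0),
            make_atom(3, "L1", "X", 3, "LIG", "B", (1.5, 3.2, 0.0), charge=-1.0,
                      lj_sigma=3.0, lj_epsilon=0.1, radius=1.8, mass=12.0),
        ]
    )


class TestSingleTrajectory:
    def test_replicated_frames_equal_single_frame(self):
        c = _bound_complex()
        one = Trajectory(c.coords[None], 10.0, c)
        three = Trajectory(np.repeat(c.coords[None], 3, axis=0), 10.0, c)
        kw = dict(pb_spacing=0.6, sasa_points=960)
        a = mmpbsa_single_trajectory(one, [0, 1], [2], **kw)
        b = mmpbsa_single_trajectory(three, [0, 1], [2], **kw)
        for term, val in a.as_dict().items():
            assert val == pytest.approx(b.as_dict()[term], abs=1e-9)
        assert b.standard_errors["delta_E_ele"] == pytest.approx(0.0, abs=1e-9)

    def test_components_match_their_oracles_on_one_frame(self):
        c = _bound_complex()
        traj = Trajectory(c.coords[None], 10.0, c)
        params = SolvationParameters()
        res = mmpbsa_single_trajectory(traj, [0, 1], [2], params, pb_spacing=0.5)
        rec, lig = c.subset([0, 1]), c.subset([2])
        assert res.delta_E_ele == pytest.approx(coulomb_energy(rec, lig), rel=1e-10)
        assert res.delta_E_vdw == pytest.approx(lennard_jones_energy(rec, lig), rel=1e-10)
        assert res.delta_G_pol == pytest.approx(
            polar_binding_component(c, [0, 1], [2], params, spacing=0.5), rel=1e-6
        )
        nonpol_direct = (
            nonpolar_solvation(shrake_rupley_sasa(c, params).total, params)
            - nonpolar_solvation(shrake_rupley_sasa(rec, params).total, params)
            - nonpolar_solvation(shrake_rupley_sasa(lig, params).total, params)
        )
        assert res.delta_G_nonpol == pytest.approx(nonpol_direct, rel=1e-10)
        assert res.delta_G_bind == pytest.approx(
            res.delta_E_ele + res.delta_E_vdw + res.delta_G_pol + res.delta_G_nonpol
            + res.minus_T_delta_S,
            abs=1e-9,
        )

    def test_separated_rigid_species_bind_with_zero_free_energy(self):
        """Far-apart neutral species with no buried surface: every binding
        term vanishes (beta set to zero so the surface offset cancels)."""
        atoms = [
            make_atom(1, "R1", "X", 1, "REC", "A", (0.0, 0.0, 0.0), radius=1.6,
                      lj_sigma=3.0, lj_epsilon=0.05, mass=12.0),
            make_atom(2, "R2", "X", 1, "REC", "A", (1.5, 0.0, 0.0), radius=1.6,
                      lj_sigma=3.0, lj_epsilon=0.05, mass=12.0),
            make_atom(3, "L1", "X", 2, "LIG", "B", (40.0, 0.0, 0.0), radius=1.6,
                      lj_sigma=3.0, lj_epsilon=0.05, mass=12.0),
            make_atom(4, "L2", "X", 2, "LIG", "B", (41.5, 0.0, 0.0), radius=1.6,
                      lj_sigma=3.0, lj_epsilon=0.05, mass=12.0),
        ]
        c = Structure(atoms)
        traj = Trajectory(c.coords[None], 10.0, c)
        params = SolvationParameters(beta=0.0)

        def factory(species: Structure) -> ToyPotential:
            bonds = []
            coords = species.coords
            for i in range(species.n_atoms):
                for j in range(i + 1, species.n_atoms):
                    r = float(np.linalg.norm(coords[i] - coords[j]))
                    if r < 2.0:
                        bonds.append(HarmonicBond(i, j, 300.0, r))
            return ToyPotential(species.n_atoms, bonds)

        res = mmpbsa_single_trajectory(
            traj, [0, 1], [2, 3], params, pb_spacing=1.0, potential_factory=factory
        )
        assert res.delta_E_ele == pytest.approx(0.0, abs=1e-9)
        assert abs(res.delta_E_vdw) < 1e-6
        assert res.delta_G_pol == pytest.approx(0.0, abs=1e-9)  # no charges
        assert res.delta_G_nonpol == pytest.approx(0.0, abs=0.01)
        # disconnected fragments: complex entropy = sum of parts
        assert res.minus_T_delta_S == pytest.approx(0.0, abs=1e-6)
        assert res.delta_G_bind == pytest.approx(0.0, abs=0.02)

    def test_selections_must_partition(self):
        c = _bound_complex()
        traj = Trajectory(c.coords[None], 10.0, c)
        with pytest.raises(ValueError, match="partition"):
            mmpbsa_single_trajectory(traj, [0], [2])
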