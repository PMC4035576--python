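"""Intermolecular Coulomb / Lennard-Jones energies and the per-residue
decomposition of the ligand-protein interaction.

Gas-phase convention: no distance cutoff, no periodic images, dielectric
1 — the terms are evaluated on bound-complex snapshots, where a cutoff
would break the additivity of the residue decomposition.  Only
intermolecular pairs are computed, so 1-4 scaling never applies.
Lorentz-Berthelot mixing: sigma arithmetic mean, epsilon geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import K_COULOMB
from .structure import Structure, Trajectory

__all__ = [
    "EnergyComponents",
    "coulomb_energy",
    "lennard_jones_energy",
    "interaction_components",
    "per_residue_decomposition",
]

_MIN_SEPARATION = 1e-6  # A; closer pairs are treated as overlapping atoms


@dataclass
class EnergyComponents:
    """Electrostatic + van der Waals split, kcal/mol."""

    electrostatic: float
    van_der_waals: float

    @property
    def total(self) -> float:
        return self.electrostatic + self.van_der_waals


def _pair_distances(a: Structure, b: Structure) -> np.ndarray:
    r = cdist(a.coords, b.coords)
    if np.any(r < _MIN_SEPARATION):
        i, j = np.unravel_index(np.argmin(r), r.shape)
        raise ValueError(
            f"overlapping atoms: {a.atoms[i].name} and {b.atoms[j].name} at r={r[i, j]:.2e} A"
        )
    return r


def coulomb_energy(group_a: Structure, group_b: Structure) -> float:
    """Pairwise Coulomb energy between two disjoint groups, kcal/mol.

    ``E = k sum_ij q_i q_j / r_ij`` with k = 332.0637 kcal*A/(mol*e^2).
    """
    r = _pair_distances(group_a, group_b)
    return float(K_COULOMB * np.sum(np.outer(group_a.charges, group_b.charges) / r))


def lennard_jones_energy(group_a: Structure, group_b: Structure) -> float:
    """Pairwise 12-6 Lennard-Jones energy, kcal/mol, Lorentz-Berthelot mixed."""
    r = _pair_distances(group_a, group_b)
    sigma = 0.5 * (group_a.lj_sigmas[:, None] + group_b.lj_sigmas[None, :])
    eps = np.sqrt(np.outer(group_a.lj_epsilons, group_b.lj_epsilons))
    sr6 = (sigma / r) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def interaction_components(group_a: Structure, group_b: Structure) -> EnergyComponents:
    return EnergyComponents(
        electrostatic=coulomb_energy(group_a, group_b),
        van_der_waals=lennard_jones_energy(group_a, group_b),
    )


def per_residue_decomposition(
    trajectory: Trajectory,
    ligand_selection,
    residue_list=None,
) -> pd.DataFrame:
    """Trajectory-mean ligand interaction energy per residue.

    Returns a DataFrame indexed by residue label with columns
    ``elec_kcal_mol, vdw_kcal_mol, total_kcal_mol`` and matching
    ``*_stderr`` columns (standard error of the frame mean).  Residues
    default to every non-ligand residue; the sum of the residue totals
    equals the whole-protein ligand interaction energy in every frame by
    construction (no cutoff).
    """
    top = trajectory.topology
    lig_idx = np.asarray(ligand_selection, dtype=int)
    if lig_idx.size == 0:
        raise ValueError("empty ligand selection")
    lig_set = set(lig_idx.tolist())
    if residue_list is None:
        residue_list = [
            key
            for key, idx in top.residue_index.items()
            if not any(int(i) in lig_set for i in idx)
        ]
    res_indices = []
    for key in residue_list:
        if len(key) == 2:
            key = (key[0], key[1], "")
        idx = top.residue_index[key]
        if any(int(i) in lig_set for i in idx):
            raise ValueError(f"residue {key} overlaps the ligand selection")
        res_indices.append((key, np.asarray(idx, dtype=int)))

    prot_idx = np.concatenate([idx for _, idx in res_indices])
    q = top.charges
    sig = top.lj_sigmas
    eps = top.lj_epsilons
    qq = K_COULOMB * np.outer(q[lig_idx], q[prot_idx])
    sigma = 0.5 * (sig[lig_idx, None] + sig[None, prot_idx])
    epsm = np.sqrt(np.outer(eps[lig_idx], eps[prot_idx]))

    # column slices per residue within prot_idx
    bounds = np.cumsum([0] + [idx.size for _, idx in res_indices])
    n_frames = trajectory.n_frames
    elec = np.empty((n_frames, len(res_indices)))
    vdw = np.empty((n_frames, len(res_indices)))
    for f in range(n_frames):
        frame = trajectory.coordinates[f]
        r = cdist(frame[lig_idx], frame[prot_idx])
        if np.any(r < _MIN_SEPARATION):
            raise ValueError(f"overlapping ligand/protein atoms in frame {f}")
        e_mat = qq / r
        sr6 = (sigma / r) ** 6
        v_mat = 4.0 * epsm * (sr6 * sr6 - sr6)
        for k in range(len(res_indices)):
            sl = slice(bounds[k], bounds[k + 1])
            elec[f, k] = e_mat[:, sl].sum()
            vdw[f, k] = v_mat[:, sl].sum()

    def stderr(x: np.ndarray) -> np.ndarray:
        if n_frames == 1:
            return np.zeros(x.shape[1])
        return x.std(axis=0, ddof=1) / np.sqrt(n_frames)

    labels = [
        f"{top.atoms[idx[0]].residue_name}{key[1]}{key[2]}".strip()
        for key, idx in res_indices
    ]
    df = pd.DataFrame(
        {
            "elec_kcal_mol": elec.mean(axis=0),
            "vdw_kcal_mol": vdw.mean(axis=0),
            "total_kcal_mol": (elec + vdw).mean(axis=0),
            "elec_stderr": stderr(elec),
            "vdw_stderr": stderr(vdw),
            "total_stderr": stderr(elec + vdw),
        },
        index=pd.Index(labels, name="residue"),
    )
    return df
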