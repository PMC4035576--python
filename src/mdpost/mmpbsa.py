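"""MM-PBSA binding free energy, single-trajectory protocol.

Receptor and ligand coordinates are cut from complex snapshots, so all
intramolecular terms cancel identically and the binding free energy
reduces to six terms,

    dG_bind = dE_ele + dE_vdw + dG_pol + dG_nonpol - T dS,

with dE_MM = dE_ele + dE_vdw (gas-phase interaction energies),
dG_sol = dG_pol + dG_nonpol (finite-difference PB + linear surface
term), and the entropy from normal-mode analysis of minimized
snapshots on its own, sparser stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .energy import coulomb_energy, lennard_jones_energy
from .entropy import normal_mode_entropy
from .minimize import MinimizationResult, ToyPotential, minimize_structure
from .pb import GridBox, solve_linear_pb
from .solvation import SolvationParameters, nonpolar_solvation, shrake_rupley_sasa
from .structure import Structure, Trajectory

__all__ = ["BindingFreeEnergy", "assemble_binding_free_energy", "mmpbsa_single_trajectory"]

_TERMS = ("delta_E_ele", "delta_E_vdw", "delta_G_pol", "delta_G_nonpol", "minus_T_delta_S")


@dataclass
class BindingFreeEnergy:
    """Six-term MM-PBSA decomposition, kcal/mol, with per-term standard errors."""

    delta_E_ele: float
    delta_E_vdw: float
    delta_G_pol: float
    delta_G_nonpol: float
    minus_T_delta_S: float
    standard_errors: dict[str, float] = field(default_factory=dict)

    @property
    def delta_E_MM(self) -> float:
        return self.delta_E_ele + self.delta_E_vdw

    @property
    def delta_G_sol(self) -> float:
        return self.delta_G_pol + self.delta_G_nonpol

    @property
    def delta_G_bind(self) -> float:
        return (
            self.delta_E_ele
            + self.delta_E_vdw
            + self.delta_G_pol
            + self.delta_G_nonpol
            + self.minus_T_delta_S
        )

    def as_dict(self) -> dict[str, float]:
        d = {t: getattr(self, t) for t in _TERMS}
        d["delta_G_bind"] = self.delta_G_bind
        return d


def assemble_binding_free_energy(components) -> BindingFreeEnergy:
    """Assemble the six-term result from the five components.

    ``components`` is a mapping with keys ``delta_E_ele, delta_E_vdw,
    delta_G_pol, delta_G_nonpol, minus_T_delta_S`` or a sequence in that
    order.  All terms must be finite.
    """
    if isinstance(components, BindingFreeEnergy):
        values = {t: getattr(components, t) for t in _TERMS}
    elif isinstance(components, dict):
        missing = [t for t in _TERMS if t not in components]
        if missing:
            raise ValueError(f"missing component(s): {', '.join(missing)}")
        values = {t: float(components[t]) for t in _TERMS}
    else:
        seq = list(components)
        if len(seq) != len(_TERMS):
            raise ValueError(f"expected {len(_TERMS)} components, got {len(seq)}")
        values = dict(zip(_TERMS, (float(v) for v in seq)))
    for name, v in values.items():
        if not np.isfinite(v):
            raise ValueError(f"component {name} is not finite: {v}")
    return BindingFreeEnergy(**values)


def _stderr(samples: np.ndarray) -> float:
    if samples.size <= 1:
        return 0.0
    return float(samples.std(ddof=1) / np.sqrt(samples.size))


def mmpbsa_single_trajectory(
    trajectory: Trajectory,
    receptor_selection,
    ligand_selection,
    parameters: SolvationParameters | None = None,
    snapshot_stride: int = 1,
    entropy_stride: int | None = None,
    pb_spacing: float = 0.5,
    pb_margin: float = 5.0,
    sasa_points: int = 960,
    potential_factory: Callable[[Structure], ToyPotential] | None = None,
    minimize_max_steps: int = 10000,
    temperature: float = 300.0,
) -> BindingFreeEnergy:
    """Run the full MM-PBSA battery over a complex trajectory.

    ``receptor_selection`` and ``ligand_selection`` must partition the
    solute.  MM, PB and SASA terms are evaluated every
    ``snapshot_stride`` frames; the entropy term every
    ``entropy_stride`` frames (default: same as snapshots) after
    minimization under the potential built by ``potential_factory`` for
    each species.  Without a ``potential_factory`` the ``-T dS`` term is
    reported as 0 — analysis trajectories carry no bonded topology.
    """
    parameters = parameters or SolvationParameters()
    rec_idx = np.asarray(receptor_selection, dtype=int)
    lig_idx = np.asarray(ligand_selection, dtype=int)
    joined = np.sort(np.concatenate([rec_idx, lig_idx]))
    if joined.size != trajectory.n_atoms or np.any(joined != np.arange(joined.size)):
        raise ValueError("receptor and ligand selections must partition the complex")
    if snapshot_stride < 1:
        raise ValueError("snapshot_stride must be >= 1")
    entropy_stride = entropy_stride or snapshot_stride

    snap_frames = range(0, trajectory.n_frames, snapshot_stride)
    ele, vdw, pol, nonpol = [], [], [], []
    for f in snap_frames:
        frame = trajectory.frame_structure(f)
        rec = frame.subset(rec_idx)
        lig = frame.subset(lig_idx)
        ele.append(coulomb_energy(rec, lig))
        vdw.append(lennard_jones_energy(rec, lig))
        box = GridBox.around(frame, pb_spacing, pb_margin)
        e_c = solve_linear_pb(frame, parameters, pb_spacing, box=box)
        e_r = solve_linear_pb(rec, parameters, pb_spacing, box=box)
        e_l = solve_linear_pb(lig, parameters, pb_spacing, box=box)
        pol.append(e_c - e_r - e_l)
        sas_c = shrake_rupley_sasa(frame, parameters, sasa_points).total
        sas_r = shrake_rupley_sasa(rec, parameters, sasa_points).total
        sas_l = shrake_rupley_sasa(lig, parameters, sasa_points).total
        nonpol.append(
            nonpolar_solvation(sas_c, parameters)
            - nonpolar_solvation(sas_r, parameters)
            - nonpolar_solvation(sas_l, parameters)
        )

    tds = []
    if potential_factory is not None:
        for f in range(0, trajectory.n_frames, entropy_stride):
            frame = trajectory.frame_structure(f)
            contributions = []
            for species in (frame, frame.subset(rec_idx), frame.subset(lig_idx)):
                pot = potential_factory(species)
                mini: MinimizationResult = minimize_structure(
                    species, pot, max_steps=minimize_max_steps
                )
                contributions.append(
                    normal_mode_entropy(mini.structure, pot, temperature=temperature)
                )
            tds.append(contributions[0] - contributions[1] - contributions[2])

    ele, vdw, pol, nonpol = map(np.asarray, (ele, vdw, pol, nonpol))
    tds = np.asarray(tds) if tds else np.zeros(1)
    result = BindingFreeEnergy(
        delta_E_ele=float(ele.mean()),
        delta_E_vdw=float(vdw.mean()),
        delta_G_pol=float(pol.mean()),
        delta_G_nonpol=float(nonpol.mean()),
        minus_T_delta_S=float(tds.mean()),
        standard_errors={
            "delta_E_ele": _stderr(ele),
            "delta_E_vdw": _stderr(vdw),
            "delta_G_pol": _stderr(pol),
            "delta_G_nonpol": _stderr(nonpol),
            "minus_T_delta_S": _stderr(tds),
        },
    )
    return result
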