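"""Synthetic inputs with known ground truth.

Every downstream analysis stage gets an oracle here:

* :func:`generate_gnm_ensemble` — Gaussian-network-model ensembles whose
  positional covariance is analytic, ``(k_B T / k) * pinv(Kirchhoff)``
  per Cartesian axis, for testing superposition statistics, DCCM and PCA.
* :func:`generate_hbond_trajectory` — frame-scripted donor/H/acceptor
  geometries with an exact target occupancy.
* :func:`generate_toy_complex` — small charged receptor/ligand pairs for
  brute-force energy checks.
* :func:`generate_born_sphere` — the canonical one-atom input whose polar
  solvation energy has a closed form.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import K_BOLTZMANN
from .structure import Atom, Structure, Trajectory

__all__ = [
    "HarmonicEnsembleSpec",
    "HBondScheduleSpec",
    "generate_gnm_ensemble",
    "generate_hbond_trajectory",
    "generate_toy_complex",
    "generate_born_sphere",
    "kirchhoff_matrix",
    "gnm_site_covariance",
]


@dataclass
class HarmonicEnsembleSpec:
    """Gaussian-network ensemble: N sites fluctuating about a reference.

    ``spring_constant`` is kcal/mol/A^2; contacts come from an explicit
    edge list or a distance cutoff on the reference coordinates.
    """

    reference: np.ndarray  # (N, 3) A
    spring_constant: float = 1.0
    temperature: float = 300.0
    n_frames: int = 1000
    seed: int = 0
    contact_cutoff: float | None = 7.0
    edges: Sequence[tuple[int, int]] | None = None
    time_stride: float = 10.0  # ps

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float).reshape(-1, 3)


@dataclass
class HBondScheduleSpec:
    """Scripted donor-H-acceptor trajectory with exact target occupancy.

    Geometries are (donor-acceptor distance A, D-H...A angle deg at the
    hydrogen); the bonded one must satisfy, and the broken one violate,
    the geometric criteria.
    """

    bonded_geometry: tuple[float, float] = (2.9, 160.0)
    broken_geometry: tuple[float, float] = (4.5, 100.0)
    occupancy: float = 0.5
    n_frames: int = 1000
    seed: int = 0
    max_distance: float = 3.5  # A, criterion the geometries are validated against
    min_angle: float = 120.0  # deg
    time_stride: float = 10.0


def kirchhoff_matrix(spec: HarmonicEnsembleSpec) -> np.ndarray:
    """Kirchhoff (connectivity) matrix of the coupling graph."""
    n = spec.reference.shape[0]
    gamma = np.zeros((n, n))
    if spec.edges is not None:
        pairs = [(int(i), int(j)) for i, j in spec.edges]
    else:
        if spec.contact_cutoff is None:
            raise ValueError("need either edges or a contact cutoff")
        d = np.linalg.norm(spec.reference[:, None] - spec.reference[None, :], axis=-1)
        ii, jj = np.where((d <= spec.contact_cutoff) & (d > 0))
        pairs = [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]
    for i, j in pairs:
        gamma[i, j] -= 1.0
        gamma[j, i] -= 1.0
        gamma[i, i] += 1.0
        gamma[j, j] += 1.0
    return gamma


def gnm_site_covariance(spec: HarmonicEnsembleSpec) -> np.ndarray:
    """Analytic per-axis site covariance ``(k_B T / k) * pinv(Kirchhoff)``."""
    gamma = kirchhoff_matrix(spec)
    w, v = np.linalg.eigh(gamma)
    tol = 1e-8 * max(w[-1], 1.0)
    n_zero = int(np.sum(w < tol))
    if n_zero != 1:
        raise ValueError(
            "coupling graph is disconnected: covariance is undefined up to rigid modes"
        )
    inv = np.zeros_like(w)
    inv[n_zero:] = 1.0 / w[n_zero:]
    return (K_BOLTZMANN * spec.temperature / spec.spring_constant) * (v * inv) @ v.T


def _ca_topology(reference: np.ndarray) -> Structure:
    atoms = [
        Atom(
            serial=i + 1,
            name="CA",
            element="C",
            residue_number=i + 1,
            residue_name="GLY",
            chain="A",
            position=reference[i],
            mass=12.011,
        )
        for i in range(reference.shape[0])
    ]
    return Structure(atoms)


def generate_gnm_ensemble(spec: HarmonicEnsembleSpec) -> Trajectory:
    """Draw a harmonic ensemble with the GNM covariance.

    Each Cartesian axis of each site is displaced independently with
    covariance ``(k_B T / k) * pinv(Gamma)`` over sites; the rigid-body
    (zero) mode is excluded, so frames fluctuate about the reference
    with no net drift.
    """
    if spec.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    gamma = kirchhoff_matrix(spec)
    w, v = np.linalg.eigh(gamma)
    tol = 1e-8 * max(w[-1], 1.0)
    if int(np.sum(w < tol)) != 1:
        raise ValueError(
            "coupling graph is disconnected: covariance is undefined up to rigid modes"
        )
    modes = v[:, 1:]  # drop the single zero mode
    std = np.sqrt(K_BOLTZMANN * spec.temperature / (spec.spring_constant * w[1:]))
    rng = np.random.default_rng(spec.seed)
    n_sites = spec.reference.shape[0]
    coords = np.empty((spec.n_frames, n_sites, 3))
    for axis in range(3):
        z = rng.standard_normal((spec.n_frames, len(std)))
        coords[:, :, axis] = spec.reference[:, axis] + (z * std) @ modes.T
    return Trajectory(coords, spec.time_stride, _ca_topology(spec.reference))


def _hbond_frame(distance: float, angle_deg: float) -> np.ndarray:
    """Donor at origin, H at (1,0,0); acceptor placed in the xy-plane so the
    D-A distance and the D-H...A angle at the hydrogen hit their targets."""
    theta = np.deg2rad(angle_deg)
    c = np.cos(theta)
    disc = c * c - 1.0 + distance * distance
    if disc < 0:
        raise ValueError(f"geometry unreachable: d={distance}, angle={angle_deg}")
    r = c + np.sqrt(disc)  # H-A distance
    acceptor = np.array([1.0 - r * c, r * np.sin(theta), 0.0])
    return np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], acceptor])


def generate_hbond_trajectory(spec: HBondScheduleSpec) -> Trajectory:
    """Scripted H-bond trajectory: exactly ``round(occupancy * n_frames)``
    bonded frames, order shuffled by the seed."""
    if not 0.0 <= spec.occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    if spec.n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    def satisfies(geom: tuple[float, float]) -> bool:
        d, a = geom
        return d < spec.max_distance and a > spec.min_angle

    if not satisfies(spec.bonded_geometry):
        raise ValueError(f"bonded geometry {spec.bonded_geometry} fails the criteria")
    if satisfies(spec.broken_geometry):
        raise ValueError(f"broken geometry {spec.broken_geometry} satisfies the criteria")

    bonded = _hbond_frame(*spec.bonded_geometry)
    broken = _hbond_frame(*spec.broken_geometry)
    n_bonded = int(round(spec.occupancy * spec.n_frames))
    flags = np.zeros(spec.n_frames, dtype=bool)
    flags[:n_bonded] = True
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(flags)
    coords = np.where(flags[:, None, None], bonded[None], broken[None])

    atoms = [
        Atom(1, "N", "N", 1, "DON", "A", bonded[0], mass=14.007),
        Atom(2, "H", "H", 1, "DON", "A", bonded[1], mass=1.008),
        Atom(3, "O", "O", 2, "ACC", "A", bonded[2], mass=15.999),
    ]
    return Trajectory(coords, spec.time_stride, Structure(atoms))


_DEFAULT_PARAMS: tuple[Mapping[str, float], ...] = (
    {"charge": 0.4, "sigma": 3.0, "epsilon": 0.10, "radius": 1.7, "mass": 12.011},
    {"charge": -0.4, "sigma": 2.9, "epsilon": 0.15, "radius": 1.55, "mass": 14.007},
    {"charge": 0.2, "sigma": 3.1, "epsilon": 0.08, "radius": 1.6, "mass": 15.999},
)


def generate_toy_complex(
    n_receptor_atoms: int,
    ligand_atoms: int,
    parameter_table: Sequence[Mapping[str, float]] | None = None,
    seed: int = 0,
    min_separation: float = 1.5,
    box: float = 8.0,
    max_retries: int = 2000,
) -> Structure:
    """Random small receptor/ligand complex with resolved parameters.

    Receptor atoms (chain A, residues of three atoms, resname REC) fill a
    cube of side ``box`` A; ligand atoms (chain B, resname LIG) are placed
    adjacent.  No two atoms end up closer than ``min_separation`` A.
    Parameters cycle through ``parameter_table``.
    """
    if n_receptor_atoms < 1:
        raise ValueError("need at least one receptor atom")
    if ligand_atoms < 1:
        raise ValueError("need at least one ligand atom")
    params = list(parameter_table) if parameter_table is not None else list(_DEFAULT_PARAMS)
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    for k in range(n_receptor_atoms + ligand_atoms):
        lo = np.zeros(3) if k < n_receptor_atoms else np.array([box * 0.5, 0.0, 0.0])
        for attempt in range(max_retries + 1):
            if attempt == max_retries:
                raise RuntimeError(
                    f"could not place atom {k} without overlap after {max_retries} tries"
                )
            pos = lo + rng.uniform(0.0, box, size=3)
            if all(np.linalg.norm(pos - q) >= min_separation for q in placed):
                placed.append(pos)
                break
    atoms = []
    for k, pos in enumerate(placed):
        row = params[k % len(params)]
        is_ligand = k >= n_receptor_atoms
        local = k - n_receptor_atoms if is_ligand else k
        atoms.append(
            Atom(
                serial=k + 1,
                name=(f"L{local + 1}" if is_ligand else f"C{local % 3 + 1}"),
                element="C",
                residue_number=(1000 if is_ligand else local // 3 + 1),
                residue_name=("LIG" if is_ligand else "REC"),
                chain=("B" if is_ligand else "A"),
                position=pos,
                charge=float(row["charge"]),
                lj_sigma=float(row["sigma"]),
                lj_epsilon=float(row["epsilon"]),
                radius=float(row["radius"]),
                mass=float(row["mass"]),
            )
        )
    return Structure(atoms)


def generate_born_sphere(charge: float, radius: float) -> Structure:
    """Single charged sphere at the origin — the closed-form PB oracle."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atom = Atom(
        serial=1,
        name="Q",
        element="X",
        residue_number=1,
        residue_name="ION",
        chain="A",
        position=np.zeros(3),
        charge=float(charge),
        radius=float(radius),
        mass=1.0,
    )
    return Structure([atom])
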