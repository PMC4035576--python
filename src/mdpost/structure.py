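"""Domain containers: atoms, structures, trajectories and force-field parameters.

A :class:`Structure` is an ordered list of :class:`Atom` records with a
residue index; a :class:`Trajectory` is a (frames, atoms, 3) coordinate
array tied to a topology :class:`Structure`.  Coordinates are Angstrom
throughout; nanometre thresholds from the literature are converted once
at the configuration boundary, never inside analysis code.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ForceFieldParameters",
    "ResidueKey",
]

#: (chain, residue_number, insertion_code) — uniquely identifies a residue.
ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    """One atom with coordinates and (optional) force-field parameters.

    ``charge`` is in elementary charges, ``lj_sigma``/``radius`` in
    Angstrom, ``lj_epsilon`` in kcal/mol, ``mass`` in amu.  Parameters
    default to zero and are filled in by
    :meth:`ForceFieldParameters.apply`.
    """

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    position: np.ndarray
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0
    radius: float = 0.0
    mass: float = 0.0
    icode: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.residue_number, self.icode)


class Structure:
    """Ordered atom collection with a residue index.

    Atom order is stable under write/read round-trips.  The residue
    index maps ``(chain, residue_number, icode)`` to the (order
    preserving) integer indices of that residue's atoms.
    """

    def __init__(self, atoms: Sequence[Atom], validate: bool = True):
        self.atoms: list[Atom] = list(atoms)
        if validate:
            seen: set[tuple[str, int, str, str]] = set()
            for a in self.atoms:
                key = (a.chain, a.residue_number, a.icode, a.name)
                if key in seen:
                    raise ValueError(
                        f"duplicate atom {a.name} in residue "
                        f"{a.chain}{a.residue_number}{a.icode}"
                    )
                seen.add(key)
        self._coords: np.ndarray | None = None
        self._residue_index: dict[ResidueKey, np.ndarray] | None = None

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, i: int) -> Atom:
        return self.atoms[i]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, Angstrom. Cached; invalidate with
        :meth:`set_coords` after moving atoms."""
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected ({self.n_atoms}, 3) coordinates, got {coords.shape}")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()
        self._coords = coords.copy()

    @property
    def residue_index(self) -> dict[ResidueKey, np.ndarray]:
        if self._residue_index is None:
            idx: dict[ResidueKey, list[int]] = {}
            for i, a in enumerate(self.atoms):
                idx.setdefault(a.residue_key, []).append(i)
            self._residue_index = {k: np.asarray(v, dtype=int) for k, v in idx.items()}
        return self._residue_index

    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys in order of first appearance."""
        return list(self.residue_index)

    def subset(self, indices: Iterable[int]) -> "Structure":
        """New Structure containing the selected atoms (order preserved)."""
        idx = np.asarray(list(indices), dtype=int)
        return Structure([_copy_atom(self.atoms[i]) for i in idx], validate=False)

    def copy(self) -> "Structure":
        return Structure([_copy_atom(a) for a in self.atoms], validate=False)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        s = self.copy()
        s.set_coords(coords)
        return s

    # -- bulk parameter views ----------------------------------------
    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def lj_sigmas(self) -> np.ndarray:
        return np.array([a.lj_sigma for a in self.atoms])

    @property
    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])


def _copy_atom(a: Atom) -> Atom:
    return replace(a, position=a.position.copy())


@dataclass
class Trajectory:
    """Frames of coordinates for a fixed atom set.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Angstrom;
    ``time_stride`` is the sampling interval in ps.
    """

    coordinates: np.ndarray
    time_stride: float
    topology: Structure

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coordinates.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def frame_structure(self, i: int) -> Structure:
        """Topology with the coordinates of frame ``i``."""
        return self.topology.with_coords(self.coordinates[i])

    def atom_subset(self, indices: Iterable[int]) -> "Trajectory":
        idx = np.asarray(list(indices), dtype=int)
        return Trajectory(self.coordinates[:, idx], self.time_stride, self.topology.subset(idx))

    @property
    def duration_ps(self) -> float:
        return (self.n_frames - 1) * self.time_stride


_PARAM_FIELDS = ("charge", "sigma", "epsilon", "radius", "mass")


class ForceFieldParameters:
    """Per-(residue, atom) nonbonded parameters with a combination rule tag.

    The table maps ``(residue_name, atom_name)`` to a dict with keys
    ``charge, sigma, epsilon, radius, mass``; a residue name of ``"*"``
    acts as a wildcard fallback.  Lorentz–Berthelot mixing is the only
    combination rule used by the energy code.
    """

    def __init__(
        self,
        table: Mapping[tuple[str, str], Mapping[str, float]],
        combination_rule: str = "lorentz-berthelot",
    ):
        self.table = {
            (r, a): {f: float(row[f]) for f in _PARAM_FIELDS} for (r, a), row in table.items()
        }
        self.combination_rule = combination_rule

    def lookup(self, residue_name: str, atom_name: str) -> dict[str, float]:
        for key in ((residue_name, atom_name), ("*", atom_name)):
            if key in self.table:
                return self.table[key]
        raise KeyError(f"no parameters for atom {atom_name!r} in residue {residue_name!r}")

    def apply(self, structure: Structure) -> Structure:
        """Return a copy of ``structure`` with parameters resolved for every atom."""
        out = structure.copy()
        for a in out.atoms:
            row = self.lookup(a.residue_name, a.name)
            a.charge = row["charge"]
            a.lj_sigma = row["sigma"]
            a.lj_epsilon = row["epsilon"]
            a.radius = row["radius"]
            a.mass = row["mass"]
        return out

    # -- I/O ----------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "ForceFieldParameters":
        table = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                table[(row["residue_name"], row["atom_name"])] = {
                    f: float(row[f]) for f in _PARAM_FIELDS
                }
        return cls(table)

    @classmethod
    def from_json(cls, path: str | Path) -> "ForceFieldParameters":
        with open(path) as fh:
            data = json.load(fh)
        table = {
            (row["residue_name"], row["atom_name"]): {f: float(row[f]) for f in _PARAM_FIELDS}
            for row in data["parameters"]
        }
        return cls(table, data.get("combination_rule", "lorentz-berthelot"))

    def to_json(self, path: str | Path) -> None:
        rows = [
            {"residue_name": r, "atom_name": a, **vals} for (r, a), vals in self.table.items()
        ]
        with open(path, "w") as fh:
            json.dump({"combination_rule": self.combination_rule, "parameters": rows}, fh, indent=1)
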