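"""Structure and trajectory I/O.

Reading goes through MDAnalysis (PDB, multi-model PDB, DCD, XTC); PDB
writing uses the fixed-column format directly so round-trips are stable
at format precision (3 decimals on coordinates).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import Atom, Structure, Trajectory

__all__ = [
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "to_universe",
]


class PDBParseError(ValueError):
    """Raised for malformed ATOM/HETATM records; message names the line."""


def _validate_pdb_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: truncated {rec} record at line {lineno}")
            try:
                int(line[6:11])
                int(line[22:26])
                for c in range(3):
                    float(line[30 + 8 * c : 38 + 8 * c])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}: malformed {rec} record at line {lineno}: {exc}"
                ) from None


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Na", "Mg", "Zn", "Fe"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


def _universe_to_structure(u) -> Structure:
    ag = u.atoms
    n = len(ag)
    serials = getattr(ag, "ids", np.arange(1, n + 1))
    icodes = getattr(ag, "icodes", np.full(n, ""))
    chains = getattr(ag, "chainIDs", np.full(n, "A"))
    try:
        elements = ag.elements
    except Exception:
        elements = [_element_from_name(nm) for nm in ag.names]
    atoms = [
        Atom(
            serial=int(serials[i]),
            name=str(ag.names[i]),
            element=str(elements[i]).strip() or _element_from_name(str(ag.names[i])),
            residue_number=int(ag.resids[i]),
            residue_name=str(ag.resnames[i]),
            chain=str(chains[i]).strip() or "A",
            position=ag.positions[i],
            icode=str(icodes[i]).strip(),
        )
        for i in range(n)
    ]
    return Structure(atoms)


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Coordinates are Angstrom; insertion codes are preserved in residue
    keys; MODEL records beyond the first are ignored.  Malformed
    ATOM/HETATM records raise :class:`PDBParseError` naming the line.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if len(u.atoms) == 0:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")
    return _universe_to_structure(u)


def _format_pdb_line(a: Atom) -> str:
    if a.serial > 99999:
        raise ValueError(f"atom serial {a.serial} exceeds PDB format limit 99999")
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {a.serial:5d} {name:<4s} {a.residue_name:<3s} {a.chain[:1]:1s}"
        f"{a.residue_number:4d}{(a.icode or ' ')[:1]:1s}   "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write ``structure`` as a single-model PDB file."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    lines = [_format_pdb_line(a) for a in structure.atoms]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        fh.write("\nTER\nEND\n")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB or (via MDAnalysis) DCD/XTC."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        with open(path, "w") as fh:
            for f in range(trajectory.n_frames):
                fh.write(f"MODEL {f + 1:8d}\n")
                frame = trajectory.topology.with_coords(trajectory.coordinates[f])
                fh.write("\n".join(_format_pdb_line(a) for a in frame.atoms))
                fh.write("\nTER\nENDMDL\n")
            fh.write("END\n")
        return
    import MDAnalysis as mda

    u = to_universe(trajectory.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=trajectory.n_atoms) as w:
            for f in range(trajectory.n_frames):
                u.atoms.positions = trajectory.coordinates[f]
                u.trajectory.ts.dt = trajectory.time_stride
                w.write(u.atoms)


def read_trajectory(
    path: str | Path,
    topology: Structure,
    time_stride: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB, DCD or XTC trajectory against ``topology``.

    ``time_stride`` (ps per frame) overrides file metadata; multi-model
    PDB carries none, so the default there is 1 ps.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".pdb":
            _validate_pdb_lines(path)
            u = mda.Universe(str(path))
        else:
            u = to_universe(topology)
            u.load_new(str(path))
    if len(u.atoms) != topology.n_atoms:
        raise ValueError(
            f"{path}: trajectory has {len(u.atoms)} atoms, topology has {topology.n_atoms}"
        )
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    if time_stride is None:
        dt = getattr(u.trajectory, "dt", None)
        time_stride = float(dt) if dt else 1.0
    return Trajectory(coords, time_stride, topology)


def to_universe(structure: Structure, coordinates: np.ndarray | None = None):
    """Build an in-memory MDAnalysis Universe mirroring ``structure``.

    Used for trajectory writing and as the backend of the selection
    grammar.
    """
    import MDAnalysis as mda

    n = structure.n_atoms
    if n == 0:
        raise ValueError("cannot build a Universe from an empty structure")
    res_keys: list = []
    atom_resindex = np.empty(n, dtype=int)
    for i, a in enumerate(structure.atoms):
        key = a.residue_key
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    first_atoms = {}
    for i, a in enumerate(structure.atoms):
        first_atoms.setdefault(a.residue_key, a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(res_keys),
            atom_resindex=atom_resindex,
            residue_segindex=np.zeros(len(res_keys), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in structure.atoms])
        u.add_TopologyAttr("elements", [a.element for a in structure.atoms])
        u.add_TopologyAttr("chainIDs", [a.chain for a in structure.atoms])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("resnames", [first_atoms[k].residue_name for k in res_keys])
        u.add_TopologyAttr("icodes", [k[2] for k in res_keys])
        u.add_TopologyAttr("masses", [a.mass for a in structure.atoms])
    u.atoms.positions = structure.coords if coordinates is None else np.asarray(coordinates)
    return u
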