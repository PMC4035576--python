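"""Structure preparation: point mutation and crystal-water filtering.

Mutation is purely geometric — side-chain truncation (ASP->ALA) or
grafting an idealized methylene + carboxylate (ASP->GLU) — not a rotamer
search.  Only the two substitutions the aspartate mutagenesis workflow
needs are supported.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Structure

__all__ = ["mutate_residue", "filter_crystal_waters", "WATER_RESNAMES"]

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL"})

_BACKBONE = ("N", "CA", "C")
_CH_BOND = 1.09  # A, aliphatic C-H
_CC_BOND = 1.52  # A, sp3 C-C
_CO_BOND = 1.25  # A, carboxylate C-O
_TET_ANGLE = np.deg2rad(109.47)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry: zero-length bond vector")
    return v / n


def _perpendicular(u: np.ndarray, hint: np.ndarray) -> np.ndarray:
    p = hint - np.dot(hint, u) * u
    if np.linalg.norm(p) < 1e-6:
        hint = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(hint, u)) > 0.9:
            hint = np.array([0.0, 1.0, 0.0])
        p = hint - np.dot(hint, u) * u
    return _unit(p)


def _methyl_hydrogens(c: np.ndarray, anchor: np.ndarray, hint: np.ndarray) -> list[np.ndarray]:
    """Three H positions completing a methyl at ``c`` bonded toward ``anchor``."""
    u = _unit(c - anchor)
    v = _perpendicular(u, hint)
    w = np.cross(u, v)
    half = np.pi - _TET_ANGLE  # angle between C-anchor axis and C-H
    out = []
    for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        d = np.cos(half) * u + np.sin(half) * (np.cos(phi) * v + np.sin(phi) * w)
        out.append(c + _CH_BOND * d)
    return out


def _resolve_residue(structure: Structure, residue_key) -> tuple:
    if len(residue_key) == 2:
        residue_key = (residue_key[0], residue_key[1], "")
    if residue_key not in structure.residue_index:
        raise KeyError(f"residue {residue_key} not in structure")
    return residue_key


def mutate_residue(structure: Structure, residue_key, target_residue: str) -> Structure:
    """Mutate an aspartate in place, geometrically.

    ``ALA``: the side chain beyond CB is removed and the CB methyl is
    completed with ideal hydrogens.  ``GLU``: a CH2 is inserted between
    CB and the carboxylate, which is rebuilt with ideal bond lengths
    (C-C 1.52 A, C-O 1.25 A).  Backbone atoms are untouched.  Force-field
    parameters for the new side chain are left at zero; re-apply a
    parameter table afterwards.
    """
    target = target_residue.upper()
    if target not in ("ALA", "GLU"):
        raise ValueError(f"unsupported mutation target {target_residue!r} (ALA or GLU)")
    key = _resolve_residue(structure, residue_key)
    idx = structure.residue_index[key]
    res_atoms = {structure.atoms[i].name: structure.atoms[i] for i in idx}
    if structure.atoms[idx[0]].residue_name != "ASP":
        raise ValueError(
            f"can only mutate ASP, residue {key} is {structure.atoms[idx[0]].residue_name}"
        )
    for bb in _BACKBONE:
        if bb not in res_atoms:
            raise ValueError(f"residue {key} is missing backbone atom {bb}")
    for heavy in ("CB", "CG", "OD1", "OD2"):
        if heavy not in res_atoms:
            raise ValueError(f"ASP residue {key} is missing side-chain atom {heavy}")

    ca, cb, cg = (res_atoms[n].position for n in ("CA", "CB", "CG"))
    had_hydrogens = any(n.startswith("HB") for n in res_atoms)
    template = res_atoms["CB"]

    def new_atom(name: str, element: str, pos: np.ndarray) -> Atom:
        return Atom(
            serial=0,
            name=name,
            element=element,
            residue_number=template.residue_number,
            residue_name=target,
            chain=template.chain,
            position=np.asarray(pos, dtype=float),
            icode=template.icode,
        )

    keep_names = {"N", "H", "H1", "H2", "H3", "CA", "HA", "C", "O", "OXT", "CB"}
    new_side: list[Atom] = []
    if target == "ALA":
        if had_hydrogens:
            for k, pos in enumerate(_methyl_hydrogens(cb, ca, cg - cb), start=1):
                new_side.append(new_atom(f"HB{k}", "H", pos))
    else:  # GLU
        keep_names |= {n for n in res_atoms if n.startswith("HB")}
        d1 = _unit(cg - cb)
        n_vec = np.cross(cg - cb, ca - cb)
        if np.linalg.norm(n_vec) < 1e-6:
            n_vec = _perpendicular(d1, np.array([0.0, 0.0, 1.0]))
        n_vec = _unit(n_vec)
        m = _unit(np.cross(n_vec, d1))
        # CD at a tetrahedral-ish 111 deg from the CB-CG axis
        theta = np.deg2rad(180.0 - 111.0)
        cd = cg + _CC_BOND * (np.cos(theta) * d1 + np.sin(theta) * m)
        e1 = _unit(cd - cg)
        p = _unit(np.cross(n_vec, e1))
        # C-C-O 117 deg at CD (so O-C-O comes out at 126 deg)
        phi = np.deg2rad(180.0 - 117.0)
        oe1 = cd + _CO_BOND * (np.cos(phi) * e1 + np.sin(phi) * p)
        oe2 = cd + _CO_BOND * (np.cos(phi) * e1 - np.sin(phi) * p)
        new_side.append(new_atom("CG", "C", cg))
        new_side.append(new_atom("CD", "C", cd))
        new_side.append(new_atom("OE1", "O", oe1))
        new_side.append(new_atom("OE2", "O", oe2))
        if had_hydrogens:
            u1, u2 = _unit(cb - cg), _unit(cd - cg)
            bis = -_unit(u1 + u2)
            perp = _unit(np.cross(u2, u1))
            half = np.deg2rad(54.25)
            for k, sgn in (("HG2", 1.0), ("HG3", -1.0)):
                pos = cg + _CH_BOND * (np.cos(half) * bis + sgn * np.sin(half) * perp)
                new_side.append(new_atom(k, "H", pos))

    out_atoms: list[Atom] = []
    inserted = False
    for i, a in enumerate(structure.atoms):
        if a.residue_key != key:
            out_atoms.append(a)
            continue
        if a.name in keep_names:
            kept = Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                residue_number=a.residue_number,
                residue_name=target,
                chain=a.chain,
                position=a.position.copy(),
                charge=a.charge,
                lj_sigma=a.lj_sigma,
                lj_epsilon=a.lj_epsilon,
                radius=a.radius,
                mass=a.mass,
                icode=a.icode,
            )
            out_atoms.append(kept)
            if a.name == "CB" and not inserted:
                out_atoms.extend(new_side)
                inserted = True
    for serial, a in enumerate(out_atoms, start=1):
        a.serial = serial
    return Structure(out_atoms)


def filter_crystal_waters(structure: Structure, ligand_selection, cutoff: float) -> Structure:
    """Keep a water only if any of its atoms is within ``cutoff`` (A) of the ligand.

    ``ligand_selection`` is an integer index array (e.g. from
    :func:`mdpost.selection.select`).  Waters are recognised by residue
    name (HOH/WAT/SOL); all non-water atoms pass through untouched.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ligand_idx = np.asarray(ligand_selection, dtype=int)
    if ligand_idx.size == 0:
        raise ValueError("empty ligand selection")
    tree = cKDTree(structure.coords[ligand_idx])
    keep_residues = set()
    water_keys = set()
    for key, idx in structure.residue_index.items():
        if structure.atoms[idx[0]].residue_name not in WATER_RESNAMES:
            continue
        water_keys.add(key)
        d, _ = tree.query(structure.coords[idx])
        if np.min(d) <= cutoff:
            keep_residues.add(key)
    keep = [
        i
        for i, a in enumerate(structure.atoms)
        if a.residue_key not in water_keys or a.residue_key in keep_residues
    ]
    return structure.subset(keep)
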