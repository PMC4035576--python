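"""Shared fixtures: tiny structures built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mdpost.structure import Atom, Structure, Trajectory


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def make_atom(serial, name, element, resid, resname, chain, pos, **kw) -> Atom:
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_number=resid,
        residue_name=resname,
        chain=chain,
        position=np.asarray(pos, dtype=float),
        **kw,
    )


@pytest.fixture
def three_atom_structure() -> Structure:
    return Structure(
        [
            make_atom(1, "N", "N", 1, "GLY", "A", (0.0, 0.0, 0.0)),
            make_atom(2, "CA", "C", 1, "GLY", "A", (1.458, 0.0, 0.0)),
            make_atom(3, "C", "C", 1, "GLY", "A", (2.009, 1.42, 0.0)),
        ]
    )


def make_ideal_asp(resid: int = 181, chain: str = "A", with_hydrogens: bool = True) -> Structure:
    """An aspartate with ideal side-chain bond lengths (CB-CG 1.52, CG-OD 1.25 A)."""
    n = np.array([-1.46, 0.0, 0.0])
    ca = np.zeros(3)
    c = np.array([0.55, 1.42, 0.0])
    o = c + np.array([1.0, 0.68, 0.0]) / np.linalg.norm([1.0, 0.68, 0.0]) * 1.23
    cb = 1.52 * _unit((0.4, -0.8, 0.9))
    dirg = _unit((1.0, -0.6, 0.9))
    cg = cb + 1.52 * dirg
    p = _unit(np.cross(dirg, (0.0, 0.0, 1.0)))
    phi = np.deg2rad(180.0 - 117.0)
    od1 = cg + 1.25 * (np.cos(phi) * dirg + np.sin(phi) * p)
    od2 = cg + 1.25 * (np.cos(phi) * dirg - np.sin(phi) * p)
    atoms = [
        make_atom(1, "N", "N", resid, "ASP", chain, n),
        make_atom(2, "CA", "C", resid, "ASP", chain, ca),
        make_atom(3, "C", "C", resid, "ASP", chain, c),
        make_atom(4, "O", "O", resid, "ASP", chain, o),
        make_atom(5, "CB", "C", resid, "ASP", chain, cb),
        make_atom(6, "CG", "C", resid, "ASP", chain, cg),
        make_atom(7, "OD1", "O", resid, "ASP", chain, od1),
        make_atom(8, "OD2", "O", resid, "ASP", chain, od2),
    ]
    if with_hydrogens:
        perp = _unit(np.cross(cg - cb, ca - cb))
        for k, sgn in (("HB2", 1.0), ("HB3", -1.0)):
            atoms.append(
                make_atom(len(atoms) + 1, k, "H", resid, "ASP", chain, cb + 1.09 * sgn * perp)
            )
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure(atoms)


@pytest.fixture
def ideal_asp() -> Structure:
    return make_ideal_asp()


def make_ca_chain(n_residues: int, chain: str = "A", start_resid: int = 1) -> Structure:
    """Non-collinear Calpha-only chain (helix-like) for selections and fits."""
    i = np.arange(n_residues)
    coords = np.stack([5.0 * np.cos(0.6 * i), 5.0 * np.sin(0.6 * i), 1.5 * i], axis=1)
    return Structure(
        [
            make_atom(k + 1, "CA", "C", start_resid + k, "GLY", chain, coords[k], mass=12.011)
            for k in range(n_residues)
        ]
    )


def frozen_trajectory(structure: Structure, n_frames: int, dt: float = 10.0) -> Trajectory:
    coords = np.repeat(structure.coords[None], n_frames, axis=0)
    return Trajectory(coords, dt, structure)


@pytest.fixture
def gnm_spec_20():
    from mdpost.synthetic import HarmonicEnsembleSpec

    i = np.arange(20)
    ref = np.stack([5.0 * np.cos(0.6 * i), 5.0 * np.sin(0.6 * i), 1.5 * i], axis=1)
    return HarmonicEnsembleSpec(
        reference=ref, spring_constant=1.0, temperature=300.0, n_frames=20000, seed=7
    )


@pytest.fixture
def toy_complex():
    from mdpost.synthetic import generate_toy_complex

    return generate_toy_complex(9, 3, seed=11)
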