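"""Vibrational entropy from normal-mode analysis.

The mass-weighted Hessian is built by central finite differences of the
analytic gradient at a minimized geometry; rigid-body modes (near-zero
eigenvalues, at most six) are discarded, and each remaining frequency
contributes the quantum harmonic-oscillator entropy

    S(nu) = R [ x / (e^x - 1) - ln(1 - e^-x) ],   x = h nu / k_B T.

Rotational and translational entropy are omitted; in binding
differences they only approximately cancel, which reports should note.
The returned quantity is the ``-T S_vib`` contribution in kcal/mol.
"""

from __future__ import annotations

import numpy as np

from .constants import AMU_TO_KG, KCAL_TO_J, K_BOLTZMANN_SI, N_AVOGADRO, PLANCK_H, R_GAS
from .minimize import ToyPotential, _rms
from .structure import Structure

__all__ = [
    "mass_weighted_hessian",
    "vibrational_frequencies",
    "harmonic_entropy",
    "normal_mode_entropy",
]

#: eigenvalues below this fraction of the largest are treated as rigid modes
_RIGID_REL_TOL = 1e-6
#: conversion: (kcal/mol/A^2/amu) -> 1/s^2
_OMEGA2_SI = KCAL_TO_J / (N_AVOGADRO * AMU_TO_KG * 1e-20)


def mass_weighted_hessian(
    structure: Structure, potential: ToyPotential, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian, mass-weighted (kcal/mol/A^2/amu)."""
    masses = structure.masses
    if np.any(masses <= 0):
        raise ValueError("all atoms need positive masses for normal-mode analysis")
    x0 = structure.coords.ravel()
    n = x0.size
    hess = np.empty((n, n))
    for k in range(n):
        xp = x0.copy()
        xp[k] += step
        xm = x0.copy()
        xm[k] -= step
        gp = potential.gradient(xp).ravel()
        gm = potential.gradient(xm).ravel()
        hess[:, k] = (gp - gm) / (2.0 * step)
    hess = 0.5 * (hess + hess.T)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(masses, 3))
    return hess * np.outer(inv_sqrt_m, inv_sqrt_m)


def vibrational_frequencies(
    structure: Structure, potential: ToyPotential, step: float = 1e-4
) -> np.ndarray:
    """Vibrational frequencies nu (1/s) after removing rigid modes.

    Near-zero eigenvalues (translations/rotations: six for a rigid
    nonlinear body, five for a linear one, more when the system is a set
    of disconnected fragments) are discarded by a relative threshold; a
    genuinely negative eigenvalue (saddle point) raises.
    """
    w = np.linalg.eigvalsh(mass_weighted_hessian(structure, potential, step))
    scale = max(np.abs(w).max(), 1e-12)
    tol = _RIGID_REL_TOL * scale
    if np.any(w < -tol):
        raise ValueError(
            f"negative Hessian eigenvalue {w.min():.3e}: structure is not a minimum"
        )
    lam = w[w > tol]
    omega = np.sqrt(lam * _OMEGA2_SI)
    return omega / (2.0 * np.pi)


def harmonic_entropy(frequencies: np.ndarray, temperature: float) -> float:
    """Vibrational entropy of harmonic oscillators, kcal/mol/K."""
    if temperature <= 0:
        return 0.0
    nu = np.asarray(frequencies, dtype=float)
    nu = nu[nu > 0]
    x = PLANCK_H * nu / (K_BOLTZMANN_SI * temperature)
    x = np.minimum(x, 700.0)  # e^x overflow guard; such modes contribute ~0
    s = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(R_GAS * s.sum())


def normal_mode_entropy(
    structure: Structure,
    potential: ToyPotential,
    temperature: float = 300.0,
    grad_rms_tolerance: float = 1e-4,
    step: float = 1e-4,
) -> float:
    """``-T * S_vib`` (kcal/mol) of a minimized structure.

    Refuses structures whose RMS gradient exceeds the minimization
    tolerance — a Hessian away from a stationary point is meaningless.
    """
    grad = potential.gradient(structure.coords)
    if _rms(grad) > grad_rms_tolerance:
        raise ValueError(
            f"structure is not minimized (RMS gradient {_rms(grad):.2e} kcal/mol/A); "
            "run minimize_structure first"
        )
    freqs = vibrational_frequencies(structure, potential, step)
    return -temperature * harmonic_entropy(freqs, temperature)
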