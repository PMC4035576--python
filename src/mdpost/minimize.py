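"""Toy differentiable potentials and structure minimization.

The minimization contract mirrors the usual end-state workflow: descend
until the RMS gradient falls below a tolerance (default 1e-4
kcal/mol/A) or a step budget runs out.  The potential here is the
minimal one the entropy stage needs — harmonic bonds
``E = k (r - r0)^2`` plus optional nonbonded Coulomb/Lennard-Jones over
non-bonded pairs — not a general force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .constants import K_COULOMB
from .structure import Structure

__all__ = ["HarmonicBond", "ToyPotential", "MinimizationResult", "minimize_structure"]


@dataclass(frozen=True)
class HarmonicBond:
    """Bond term ``E = force_constant * (r - rest_length)^2`` (Amber-style
    force constant, kcal/mol/A^2)."""

    i: int
    j: int
    force_constant: float
    rest_length: float


@dataclass
class ToyPotential:
    """Harmonic bonds + optional intermolecular nonbonded terms.

    ``charges``/``lj_sigma``/``lj_epsilon`` arrays enable the nonbonded
    part over all atom pairs that are not bonded; leave them ``None``
    for a bonds-only network.
    """

    n_atoms: int
    bonds: Sequence[HarmonicBond] = field(default_factory=list)
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None
    lj_epsilon: np.ndarray | None = None

    def __post_init__(self) -> None:
        self._bonded_pairs = {(min(b.i, b.j), max(b.i, b.j)) for b in self.bonds}
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
        if self.lj_sigma is not None:
            self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        if self.lj_epsilon is not None:
            self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)

    @classmethod
    def from_structure(
        cls, structure: Structure, bonds: Sequence[HarmonicBond], nonbonded: bool = False
    ) -> "ToyPotential":
        return cls(
            n_atoms=structure.n_atoms,
            bonds=list(bonds),
            charges=structure.charges if nonbonded else None,
            lj_sigma=structure.lj_sigmas if nonbonded else None,
            lj_epsilon=structure.lj_epsilons if nonbonded else None,
        )

    # -- energy and analytic gradient ---------------------------------
    def energy_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        energy = 0.0
        grad = np.zeros_like(x)
        for b in self.bonds:
            d = x[b.i] - x[b.j]
            r = np.linalg.norm(d)
            if r < 1e-12:
                raise FloatingPointError("coincident bonded atoms")
            energy += b.force_constant * (r - b.rest_length) ** 2
            g = 2.0 * b.force_constant * (r - b.rest_length) * d / r
            grad[b.i] += g
            grad[b.j] -= g
        if self.charges is not None:
            for i in range(self.n_atoms):
                for j in range(i + 1, self.n_atoms):
                    if (i, j) in self._bonded_pairs:
                        continue
                    d = x[i] - x[j]
                    r = np.linalg.norm(d)
                    if r < 1e-6:
                        raise FloatingPointError("overlapping nonbonded atoms")
                    qq = K_COULOMB * self.charges[i] * self.charges[j]
                    energy += qq / r
                    dEdr = -qq / r**2
                    if self.lj_epsilon is not None:
                        sig = 0.5 * (self.lj_sigma[i] + self.lj_sigma[j])
                        eps = np.sqrt(self.lj_epsilon[i] * self.lj_epsilon[j])
                        sr6 = (sig / r) ** 6
                        energy += 4.0 * eps * (sr6 * sr6 - sr6)
                        dEdr += 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
                    g = dEdr * d / r
                    grad[i] += g
                    grad[j] -= g
        return float(energy), grad

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_gradient(coords)[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_gradient(coords)[1]


def _rms(grad: np.ndarray) -> float:
    return float(np.sqrt(np.mean(grad**2)))


@dataclass
class MinimizationResult:
    structure: Structure
    converged: bool
    n_steps: int
    energy: float
    grad_rms: float  # kcal/mol/A


def minimize_structure(
    structure: Structure,
    potential: ToyPotential,
    max_steps: int = 10000,
    rms_tolerance: float = 1e-4,
) -> MinimizationResult:
    """L-BFGS minimization until RMS gradient <= ``rms_tolerance``.

    Energy is non-increasing across accepted steps (Wolfe line search);
    ``max_steps=0`` returns the input unchanged with ``converged``
    reflecting whether it already satisfies the tolerance.
    """
    x0 = structure.coords.ravel()
    e0, g0 = potential.energy_gradient(x0)
    if not np.isfinite(e0):
        raise FloatingPointError("potential evaluates to a non-finite energy")
    if _rms(g0) <= rms_tolerance:
        return MinimizationResult(structure.copy(), True, 0, e0, _rms(g0))
    if max_steps == 0:
        return MinimizationResult(structure.copy(), False, 0, e0, _rms(g0))

    def fun(x):
        e, g = potential.energy_gradient(x)
        if not np.isfinite(e):
            raise FloatingPointError("potential evaluates to a non-finite energy")
        return e, g.ravel()

    res = _scipy_minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": rms_tolerance * 1e-2, "ftol": 1e-15},
    )
    e_final, g_final = potential.energy_gradient(res.x)
    out = structure.with_coords(res.x.reshape(-1, 3))
    rms = _rms(g_final)
    return MinimizationResult(out, rms <= rms_tolerance, int(res.nit), e_final, rms)
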