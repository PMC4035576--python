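"""Finite-difference linear Poisson-Boltzmann solver (zero ionic strength).

Solves ``div(eps grad phi) = -4 pi rho`` on a uniform grid with a
7-point stencil.  The dielectric lives on grid links and is harmonically
averaged over each link from sample points classified as inside/outside
the union of atomic spheres; charges are spread trilinearly; the outer
boundary carries the analytic Coulomb potential screened by the solvent
dielectric (Dirichlet).  The symmetric positive-definite system is
solved with Jacobi-preconditioned conjugate gradients.

The polar solvation energy is the reaction-field energy

    dG_pol = 1/2 sum_i q_i [phi_solvated(x_i) - phi_uniform(x_i)]

where the reference solve uses the same grid and charge spreading with
the interior dielectric everywhere, so the (spacing-dependent) grid
self-energy cancels exactly.  The canonical oracle is the Born ion:
``dG = -(k q^2 / 2R)(1/eps_in - 1/eps_out)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .constants import K_COULOMB
from .solvation import SolvationParameters
from .structure import Structure

__all__ = [
    "PBGrid",
    "GridBox",
    "solve_linear_pb",
    "polar_binding_component",
    "born_energy",
    "write_opendx",
]

#: sample points per link for the dielectric harmonic average
_LINK_SAMPLES = np.array([0.125, 0.375, 0.625, 0.875])


@dataclass
class GridBox:
    """Axis-aligned grid placement: origin (A) and node counts per axis."""

    origin: np.ndarray
    shape: tuple[int, int, int]
    spacing: float

    @classmethod
    def around(cls, structure: Structure, spacing: float, margin: float = 5.0) -> "GridBox":
        coords = structure.coords
        radii = structure.radii
        lo = (coords - radii[:, None]).min(axis=0) - margin
        hi = (coords + radii[:, None]).max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
        if min(shape) < 5:
            raise ValueError("grid too small: refine the spacing or enlarge the margin")
        return cls(origin=np.asarray(lo, dtype=float), shape=shape, spacing=float(spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )


@dataclass
class PBGrid:
    """Solved grid: potential in e/A (multiply by 332.0637 for kcal/mol/e)."""

    box: GridBox
    potential: np.ndarray  # (nx, ny, nz)


def _inside_solute(points: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean mask: point inside the union of atomic spheres."""
    inside = np.zeros(points.shape[0], dtype=bool)
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        todo = ~inside
        if not todo.any():
            break
        d2 = np.sum((points[todo] - c) ** 2, axis=1)
        inside[np.flatnonzero(todo)[d2 < r * r]] = True
    return inside


def _link_dielectric(box: GridBox, axis: int, centers, radii, eps_in, eps_out) -> np.ndarray:
    xs, ys, zs = box.axes()
    shape = list(box.shape)
    shape[axis] -= 1
    base = np.stack(
        np.meshgrid(xs[: box.shape[0] - 1] if axis == 0 else xs,
                    ys[: box.shape[1] - 1] if axis == 1 else ys,
                    zs[: box.shape[2] - 1] if axis == 2 else zs,
                    indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    inv = np.zeros(base.shape[0])
    for frac in _LINK_SAMPLES:
        pts = base.copy()
        pts[:, axis] += frac * box.spacing
        inside = _inside_solute(pts, centers, radii)
        inv += np.where(inside, 1.0 / eps_in, 1.0 / eps_out)
    return (len(_LINK_SAMPLES) / inv).reshape(shape)


def _spread_charges(box: GridBox, centers: np.ndarray, charges: np.ndarray) -> np.ndarray:
    q = np.zeros(box.shape)
    rel = (centers - box.origin) / box.spacing
    i0 = np.floor(rel).astype(int)
    frac = rel - i0
    for a in range(centers.shape[0]):
        if charges[a] == 0.0:
            continue
        ix, iy, iz = i0[a]
        fx, fy, fz = frac[a]
        if not (0 <= ix < box.shape[0] - 1 and 0 <= iy < box.shape[1] - 1 and 0 <= iz < box.shape[2] - 1):
            raise ValueError("charge outside the grid: enlarge the margin")
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    q[ix + dx, iy + dy, iz + dz] += charges[a] * wx * wy * wz
    return q


def _coulomb_potential(points: np.ndarray, centers, charges, eps) -> np.ndarray:
    phi = np.zeros(points.shape[0])
    for c, q in zip(centers, charges):
        if q == 0.0:
            continue
        r = np.linalg.norm(points - c, axis=1)
        r = np.maximum(r, 1e-6)
        phi += q / (eps * r)
    return phi


def _solve_grid(
    box: GridBox,
    centers: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    eps_in: float,
    eps_out: float,
    uniform: bool,
    rtol: float,
    maxiter: int,
) -> np.ndarray:
    nx, ny, nz = box.shape
    if uniform:
        eps_links = [np.full((nx - 1, ny, nz), eps_in),
                     np.full((nx, ny - 1, nz), eps_in),
                     np.full((nx, ny, nz - 1), eps_in)]
        eps_bc = eps_in
    else:
        eps_links = [
            _link_dielectric(box, axis, centers, radii, eps_in, eps_out) for axis in range(3)
        ]
        eps_bc = eps_out

    q_nodes = _spread_charges(box, centers, charges)

    boundary = np.zeros(box.shape, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    interior = ~boundary

    xs, ys, zs = box.axes()
    grid_pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    phi = np.zeros(box.shape)
    bpts = grid_pts[boundary].reshape(-1, 3)
    phi[boundary] = _coulomb_potential(bpts, centers, charges, eps_bc)

    idx = -np.ones(box.shape, dtype=int)
    idx[interior] = np.arange(int(interior.sum()))
    n_unknown = int(interior.sum())

    rows, cols, vals = [], [], []
    b = 4.0 * np.pi * q_nodes[interior] / box.spacing
    diag = np.zeros(n_unknown)

    offsets = [(0, (1, 0, 0)), (1, (0, 1, 0)), (2, (0, 0, 1))]
    for axis, (dx, dy, dz) in offsets:
        eps = eps_links[axis]
        # link from node n to node n+e_axis
        sl_lo = tuple(slice(0, s - d) for s, d in zip(box.shape, (dx, dy, dz)))
        sl_hi = tuple(slice(d, s) for s, d in zip(box.shape, (dx, dy, dz)))
        # eps array already has the reduced extent along `axis`
        e = eps
        lo_idx = idx[sl_lo]
        hi_idx = idx[sl_hi]
        lo_int = lo_idx >= 0
        hi_int = hi_idx >= 0
        both = lo_int & hi_int
        rows.append(lo_idx[both])
        cols.append(hi_idx[both])
        vals.append(-e[both])
        rows.append(hi_idx[both])
        cols.append(lo_idx[both])
        vals.append(-e[both])
        # diagonal contributions for any interior endpoint
        np.add.at(diag, lo_idx[lo_int], e[lo_int])
        np.add.at(diag, hi_idx[hi_int], e[hi_int])
        # boundary endpoints move to the RHS
        lo_only = lo_int & ~hi_int
        hi_only = hi_int & ~lo_int
        phi_hi = phi[sl_hi]
        phi_lo = phi[sl_lo]
        np.add.at(b, lo_idx[lo_only], e[lo_only] * phi_hi[lo_only])
        np.add.at(b, hi_idx[hi_only], e[hi_only] * phi_lo[hi_only])

    rows.append(np.arange(n_unknown))
    cols.append(np.arange(n_unknown))
    vals.append(diag)
    a_mat = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    ).tocsr()

    precond = LinearOperator((n_unknown, n_unknown), matvec=lambda x: x / diag)
    sol, info = cg(a_mat, b, rtol=rtol, maxiter=maxiter, M=precond)
    if info != 0:
        residual = float(np.linalg.norm(a_mat @ sol - b))
        raise RuntimeError(
            f"PB solver did not converge in {maxiter} iterations (residual {residual:.3e})"
        )
    phi[interior] = sol
    return phi


def _interpolate(box: GridBox, phi: np.ndarray, points: np.ndarray) -> np.ndarray:
    rel = (points - box.origin) / box.spacing
    i0 = np.floor(rel).astype(int)
    frac = rel - i0
    out = np.zeros(points.shape[0])
    for a in range(points.shape[0]):
        ix, iy, iz = i0[a]
        fx, fy, fz = frac[a]
        acc = 0.0
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    acc += wx * wy * wz * phi[ix + dx, iy + dy, iz + dz]
        out[a] = acc
    return out


def solve_linear_pb(
    structure: Structure,
    parameters: SolvationParameters | None = None,
    spacing: float = 0.4,
    margin: float = 5.0,
    box: GridBox | None = None,
    inflate_probe: bool = False,
    rtol: float = 1e-10,
    maxiter: int = 20000,
    return_grid: bool = False,
):
    """Polar (reaction-field) solvation energy of ``structure``, kcal/mol.

    The dielectric boundary is the union of the atomic spheres of the
    intrinsic radii (``inflate_probe=True`` adds the solvent probe).
    ``box`` pins the grid placement so that complex/receptor/ligand
    solves in a binding calculation share identical grids.
    """
    parameters = parameters or SolvationParameters()
    centers = structure.coords
    charges = structure.charges
    radii = structure.radii.copy()
    if np.any(radii <= 0):
        raise ValueError("every atom needs a positive radius for the dielectric boundary")
    if inflate_probe:
        radii = radii + parameters.probe_radius
    if box is None:
        probe_pad = parameters.probe_radius if inflate_probe else 0.0
        box = GridBox.around(structure, spacing, margin + probe_pad)
    phi_solv = _solve_grid(
        box, centers, charges, radii, parameters.eps_in, parameters.eps_out,
        uniform=False, rtol=rtol, maxiter=maxiter,
    )
    phi_ref = _solve_grid(
        box, centers, charges, radii, parameters.eps_in, parameters.eps_out,
        uniform=True, rtol=rtol, maxiter=maxiter,
    )
    dphi = _interpolate(box, phi_solv - phi_ref, centers)
    energy = 0.5 * K_COULOMB * float(np.dot(charges, dphi))
    if return_grid:
        return energy, PBGrid(box=box, potential=phi_solv)
    return energy


def polar_binding_component(
    complex_structure: Structure,
    receptor_selection,
    ligand_selection,
    parameters: SolvationParameters | None = None,
    spacing: float = 0.4,
    margin: float = 5.0,
    **solver_kwargs,
) -> float:
    """Polar binding term ``PB(complex) - PB(receptor) - PB(ligand)``.

    Receptor and ligand are coordinate subsets of the complex (the
    single-trajectory protocol) and must partition its atoms; all three
    solves share one grid placement.
    """
    rec_idx = np.asarray(receptor_selection, dtype=int)
    lig_idx = np.asarray(ligand_selection, dtype=int)
    if rec_idx.size == 0 or lig_idx.size == 0:
        raise ValueError("receptor and ligand selections must be non-empty")
    joined = np.sort(np.concatenate([rec_idx, lig_idx]))
    if joined.size != complex_structure.n_atoms or np.any(joined != np.arange(joined.size)):
        raise ValueError("receptor and ligand selections must partition the complex")
    parameters = parameters or SolvationParameters()
    box = GridBox.around(complex_structure, spacing, margin)
    e_complex = solve_linear_pb(complex_structure, parameters, spacing, box=box, **solver_kwargs)
    e_rec = solve_linear_pb(
        complex_structure.subset(rec_idx), parameters, spacing, box=box, **solver_kwargs
    )
    e_lig = solve_linear_pb(
        complex_structure.subset(lig_idx), parameters, spacing, box=box, **solver_kwargs
    )
    return e_complex - e_rec - e_lig


def born_energy(charge: float, radius: float, eps_in: float = 1.0, eps_out: float = 80.0) -> float:
    """Closed-form Born-ion polar solvation energy, kcal/mol."""
    return -K_COULOMB * charge * charge / (2.0 * radius) * (1.0 / eps_in - 1.0 / eps_out)


def write_opendx(grid: PBGrid, path) -> None:
    """Dump a solved potential as an OpenDX scalar field for inspection."""
    nx, ny, nz = grid.box.shape
    h = grid.box.spacing
    o = grid.box.origin
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}\n")
        fh.write(f"delta {h:.6f} 0 0\ndelta 0 {h:.6f} 0\ndelta 0 0 {h:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
        flat = grid.potential.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
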