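"""Dynamic cross-correlation and essential-dynamics PCA.

The DCCM element for residues i, j is

    C_ij = <dr_i . dr_j> / sqrt(<dr_i^2> <dr_j^2>)

with ``dr`` the displacement of a Calpha atom from its trajectory-mean
position after least-squares superposition; values lie in [-1, 1], the
diagonal is identically 1.  PCA diagonalises the 3N x 3N positional
covariance of the same superposed coordinates: the eigenvalue sum equals
the covariance trace (total mean-square fluctuation), and leading modes
carry the concerted motions.

Both operations are unweighted (no masses) and centre on the iterative
trajectory mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fit import align_frames_to_mean
from .structure import Trajectory

__all__ = [
    "CorrelationMatrix",
    "PCAResult",
    "cross_correlation_matrix",
    "positional_covariance",
    "pca_decompose",
    "pca_from_trajectory",
    "variance_fraction",
    "mode_displacement_profile",
]


@dataclass
class CorrelationMatrix:
    """Normalized displacement-covariance matrix with residue labels."""

    values: np.ndarray  # (N, N), dimensionless, in [-1, 1]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.values = v


@dataclass
class PCAResult:
    """Eigen-decomposition of the 3N positional covariance.

    ``eigenvalues`` (A^2) are descending; ``eigenvectors`` holds
    orthonormal columns (3N x 3N); ``mean`` is the superposed mean
    coordinates (N, 3).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.eigenvectors.shape[0] // 3


def _selected_frames(trajectory: Trajectory, selection) -> np.ndarray:
    if selection is None:
        selection = np.arange(trajectory.n_atoms)
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return trajectory.coordinates[:, idx]


def cross_correlation_matrix(
    trajectory: Trajectory, ca_selection=None, superpose: bool = True
) -> CorrelationMatrix:
    """DCCM over the selected atoms (superposition to the mean included).

    Raises if any selected atom has zero variance (the normalisation is
    undefined), naming the offending atom.  ``superpose=False`` skips
    the least-squares fit — appropriate for ensembles generated in a
    fixed frame with rigid-body modes already removed.
    """
    if ca_selection is None:
        ca_selection = np.arange(trajectory.n_atoms)
    idx = np.asarray(ca_selection, dtype=int)
    frames = _selected_frames(trajectory, idx)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames for a correlation matrix")
    aligned = align_frames_to_mean(frames) if superpose else frames
    disp = aligned - aligned.mean(axis=0)
    # inner = <dr_i . dr_j>, an (N, N) matrix
    inner = np.einsum("fia,fja->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    if np.any(var <= 0):
        bad = int(np.argmin(var))
        atom = trajectory.topology.atoms[idx[bad]]
        raise ValueError(
            f"zero-variance atom in correlation: {atom.chain}{atom.residue_number}:{atom.name}"
        )
    denom = np.sqrt(np.outer(var, var))
    values = np.clip(inner / denom, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    labels = [
        f"{trajectory.topology.atoms[i].residue_name}{trajectory.topology.atoms[i].residue_number}"
        for i in idx
    ]
    return CorrelationMatrix(values=values, labels=labels)


def positional_covariance(
    trajectory: Trajectory, selection=None, superpose: bool = True
) -> np.ndarray:
    """3N x 3N positional covariance (A^2) of the superposed selection.

    ``superpose=False`` skips the fit for fixed-frame ensembles (the
    analytic-recovery oracle): a Kabsch fit would strip the rigid-body
    component those ensembles deliberately retain in their covariance.
    """
    frames = _selected_frames(trajectory, selection)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames for a covariance matrix")
    aligned = align_frames_to_mean(frames) if superpose else frames
    flat = aligned.reshape(aligned.shape[0], -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / centered.shape[0]
    return 0.5 * (cov + cov.T)


def pca_decompose(covariance: np.ndarray, mean: np.ndarray | None = None) -> PCAResult:
    """Diagonalise a positional covariance matrix.

    Eigenvalues come back descending; each eigenvector's
    largest-magnitude component is made positive so mode signs are
    reproducible.  Input asymmetric beyond 1e-8 is rejected.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    scale = max(1.0, float(np.abs(cov).max()))
    if np.abs(cov - cov.T).max() > 1e-8 * scale:
        raise ValueError("covariance matrix is not symmetric")
    w, v = np.linalg.eigh(0.5 * (cov + cov.T))
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    return PCAResult(eigenvalues=w, eigenvectors=v, mean=mean)


def pca_from_trajectory(
    trajectory: Trajectory, selection=None, superpose: bool = True
) -> PCAResult:
    """Covariance + decomposition in one step (superposition included)."""
    frames = _selected_frames(trajectory, selection)
    aligned = align_frames_to_mean(frames) if superpose else frames
    cov = positional_covariance(trajectory, selection, superpose=superpose)
    return pca_decompose(cov, mean=aligned.mean(axis=0))


def variance_fraction(pca_result: PCAResult, k: int) -> float:
    """Percent of total fluctuation captured by the first ``k`` modes."""
    n = pca_result.eigenvalues.size
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    total = float(pca_result.eigenvalues.sum())
    if total <= 0:
        raise ValueError("covariance has no variance to apportion")
    return 100.0 * float(pca_result.eigenvalues[:k].sum()) / total


def mode_displacement_profile(
    pca_result: PCAResult, mode_index: int, scale_by_eigenvalue: bool = False
) -> np.ndarray:
    """Per-residue displacement magnitude of one eigenvector.

    Entry i is the Euclidean norm of the mode's (x, y, z) triplet for
    residue i; with ``scale_by_eigenvalue`` the profile is multiplied by
    sqrt(lambda) to show actual amplitudes rather than directions.
    """
    n_modes = pca_result.eigenvectors.shape[1]
    if not 0 <= mode_index < n_modes:
        raise ValueError(f"mode index {mode_index} out of range [0, {n_modes})")
    vec = pca_result.eigenvectors[:, mode_index].reshape(-1, 3)
    profile = np.linalg.norm(vec, axis=1)
    if scale_by_eigenvalue:
        profile = profile * np.sqrt(max(pca_result.eigenvalues[mode_index], 0.0))
    return profile
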