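"""Superposition statistics: Kabsch least-squares fit, RMSD and RMSF.

RMSD is measured against the first production frame after a Kabsch fit
on the analysis selection; RMSF is measured about the iteratively
refined mean structure (fit -> mean -> refit, two passes), so rigid-body
motion never inflates either statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "apply_superposition",
    "align_frames_to_mean",
    "rmsd_series",
    "rmsf_profile",
]


@dataclass
class SuperpositionResult:
    """Proper-rotation + translation minimising the weighted RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,) A; aligned = (mobile @ R.T) + t
    rmsd: float  # A, after the fit


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Weighted Kabsch superposition of ``mobile`` onto ``reference``.

    Reflections are excluded (the rotation determinant is forced to +1).
    Raises on fewer than three points or collinear/degenerate input.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    # degenerate geometry: points (nearly) collinear leave the rotation free
    if np.linalg.matrix_rank(y * np.sqrt(w)[:, None], tol=1e-8 * max(1.0, np.abs(y).max())) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    h = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    aligned = x @ rot.T + cr
    rmsd = float(np.sqrt(np.sum(w * np.sum((aligned - reference) ** 2, axis=1))))
    translation = cr - rot @ cm
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords) @ result.rotation.T + result.translation


def align_frames_to_mean(
    frames: np.ndarray, weights: np.ndarray | None = None, n_passes: int = 2
) -> np.ndarray:
    """Superpose every frame onto the (iteratively refined) mean.

    Pass 1 fits to the first frame and forms a mean; pass 2 refits to
    that mean.  Returns the aligned (F, N, 3) array.
    """
    frames = np.asarray(frames, dtype=float)
    aligned = frames.copy()
    target = frames[0]
    for _ in range(max(1, n_passes)):
        for f in range(frames.shape[0]):
            res = kabsch_superpose(aligned[f], target, weights)
            aligned[f] = apply_superposition(aligned[f], res)
        target = aligned.mean(axis=0)
    return aligned


def _resolve_selection(trajectory: Trajectory, selection) -> np.ndarray:
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return idx


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray | Structure | None = None,
    selection=None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A) to ``reference`` after fitting on ``selection``.

    ``reference`` defaults to the first frame; ``selection`` defaults to
    all atoms.  Returns an array of length ``n_frames``.
    """
    if selection is None:
        selection = np.arange(trajectory.n_atoms)
    idx = _resolve_selection(trajectory, selection)
    if isinstance(reference, Structure):
        ref = reference.coords
    elif reference is None:
        ref = trajectory.coordinates[0]
    else:
        ref = np.asarray(reference, dtype=float)
    ref_sel = ref[idx]
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        out[f] = kabsch_superpose(trajectory.coordinates[f, idx], ref_sel, weights).rmsd
    return out


def rmsf_profile(
    trajectory: Trajectory,
    selection=None,
    weights: np.ndarray | None = None,
    per_residue: bool = False,
    superpose: bool = True,
) -> np.ndarray:
    """Root-mean-square fluctuation (A) about the mean structure.

    ``RMSF_i = sqrt(<|r_i - <r_i>|^2>)`` after two-pass alignment to the
    mean.  With ``per_residue=True`` the per-atom values are averaged
    within each residue of the selection; ``superpose=False`` skips the
    fit for ensembles generated in a fixed frame.
    """
    if selection is None:
        selection = np.arange(trajectory.n_atoms)
    idx = _resolve_selection(trajectory, selection)
    frames = trajectory.coordinates[:, idx]
    aligned = align_frames_to_mean(frames, weights) if superpose else frames
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    if not per_residue:
        return rmsf
    keys = [trajectory.topology.atoms[i].residue_key for i in idx]
    order: list = []
    groups: dict = {}
    for pos, k in enumerate(keys):
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(pos)
    return np.array([rmsf[groups[k]].mean() for k in order])
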