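"""Geometric hydrogen-bond detection and occupancy statistics.

A donor-hydrogen-acceptor triplet counts as bonded in a frame when the
donor-acceptor distance is below 3.5 A (0.35 nm) and the D-H...A angle
measured at the hydrogen exceeds 120 degrees.  Occupancy is the
percentage of frames in which the bond exists,
``100 * N_existence / N_total``; mean distance and angle are taken over
the bonded frames only.

The angle criterion is conventionally quoted "acceptor...H-donor"; here
it is evaluated at the hydrogen (near-linear bonds score ~160-180 deg),
with a donor-centred alternative available via ``angle_at="donor"`` for
comparison.  The two conventions give different answers, deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .structure import Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "is_hbond",
    "hbond_occupancy",
    "hbond_timeseries",
    "enumerate_candidate_pairs",
]

#: maximum D-H covalent distance used to infer the donor-hydrogen bond, A
_COVALENT_DH = 1.2


@dataclass
class HBondCriteria:
    """Geometric criteria: D-A distance < ``max_distance`` (A) and the
    angle at the chosen vertex > ``min_angle_deg``."""

    max_distance: float = 3.5
    min_angle_deg: float = 120.0
    angle_at: str = "hydrogen"  # or "donor"

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0.0 < self.min_angle_deg < 180.0:
            raise ValueError("min_angle_deg must lie in (0, 180)")
        if self.angle_at not in ("hydrogen", "donor"):
            raise ValueError("angle_at must be 'hydrogen' or 'donor'")


@dataclass
class HBondRecord:
    """Per-pair summary: geometry means over bonded frames + occupancy %."""

    donor: str
    hydrogen: str
    acceptor: str
    mean_distance: float  # A, D-A, NaN if never bonded
    mean_angle: float  # deg, NaN if never bonded
    probability: float  # percent in [0, 100]


def _angle_deg(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _geometry(
    frame: np.ndarray, donor: int, hydrogen: int, acceptor: int, criteria: HBondCriteria
) -> tuple[float, float]:
    d_pos, h_pos, a_pos = frame[donor], frame[hydrogen], frame[acceptor]
    if np.linalg.norm(h_pos - d_pos) >= _COVALENT_DH:
        raise ValueError(
            f"hydrogen {hydrogen} is not covalently bonded to donor {donor} "
            f"(D-H distance >= {_COVALENT_DH} A)"
        )
    distance = float(np.linalg.norm(a_pos - d_pos))
    if criteria.angle_at == "hydrogen":
        angle = _angle_deg(h_pos, d_pos, a_pos)
    else:
        angle = _angle_deg(d_pos, h_pos, a_pos)
    return distance, angle


def is_hbond(
    frame: np.ndarray,
    donor: int,
    hydrogen: int,
    acceptor: int,
    criteria: HBondCriteria | None = None,
) -> bool:
    """Apply the geometric criteria to one frame.

    ``frame`` is an (N, 3) coordinate array; the three indices must be
    distinct and the hydrogen must sit within covalent range (1.2 A) of
    the donor.
    """
    if len({donor, hydrogen, acceptor}) != 3:
        raise ValueError("donor, hydrogen and acceptor must be three distinct atoms")
    criteria = criteria or HBondCriteria()
    distance, angle = _geometry(np.asarray(frame, dtype=float), donor, hydrogen, acceptor, criteria)
    return distance < criteria.max_distance and angle > criteria.min_angle_deg


def _atom_key(structure: Structure, i: int) -> str:
    a = structure.atoms[i]
    return f"{a.chain}:{a.residue_name}{a.residue_number}{a.icode}:{a.name}"


def hbond_occupancy(
    trajectory: Trajectory,
    pairs: list[tuple[int, int, int]],
    criteria: HBondCriteria | None = None,
) -> list[HBondRecord]:
    """Occupancy statistics for each (donor, hydrogen, acceptor) triplet.

    An empty pair list yields an empty result.  Each pair is evaluated
    independently — alternate bonds sharing a donor are not made
    mutually exclusive.
    """
    criteria = criteria or HBondCriteria()
    records: list[HBondRecord] = []
    n_total = trajectory.n_frames
    for donor, hydrogen, acceptor in pairs:
        if len({donor, hydrogen, acceptor}) != 3:
            raise ValueError("donor, hydrogen and acceptor must be three distinct atoms")
        distances = np.empty(n_total)
        angles = np.empty(n_total)
        for f in range(n_total):
            distances[f], angles[f] = _geometry(
                trajectory.coordinates[f], donor, hydrogen, acceptor, criteria
            )
        exists = (distances < criteria.max_distance) & (angles > criteria.min_angle_deg)
        n_exist = int(exists.sum())
        records.append(
            HBondRecord(
                donor=_atom_key(trajectory.topology, donor),
                hydrogen=_atom_key(trajectory.topology, hydrogen),
                acceptor=_atom_key(trajectory.topology, acceptor),
                mean_distance=float(distances[exists].mean()) if n_exist else float("nan"),
                mean_angle=float(angles[exists].mean()) if n_exist else float("nan"),
                probability=100.0 * n_exist / n_total,
            )
        )
    return records


def hbond_timeseries(
    trajectory: Trajectory,
    pair: tuple[int, int, int],
    criteria: HBondCriteria | None = None,
    stride_ps: float | None = None,
) -> np.ndarray:
    """Existence (0/1) of one bond sampled every ``stride_ps``.

    The stride must be an integer multiple of the trajectory's native
    time stride; sampling starts at the first frame, so a trajectory of
    F frames yields ``ceil(F / step)`` samples.
    """
    criteria = criteria or HBondCriteria()
    stride_ps = trajectory.time_stride if stride_ps is None else stride_ps
    ratio = stride_ps / trajectory.time_stride
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-9:
        raise ValueError(
            f"stride {stride_ps} ps is not a multiple of the native stride "
            f"{trajectory.time_stride} ps"
        )
    donor, hydrogen, acceptor = pair
    out = np.zeros(ceil(trajectory.n_frames / step), dtype=bool)
    for k, f in enumerate(range(0, trajectory.n_frames, step)):
        out[k] = is_hbond(trajectory.coordinates[f], donor, hydrogen, acceptor, criteria)
    return out


_POLAR_ELEMENTS = {"N", "O"}


def enumerate_candidate_pairs(
    trajectory: Trajectory, search_cutoff: float = 4.0
) -> list[tuple[int, int, int]]:
    """Auto-enumerate candidate triplets: N/O donors with an attached
    hydrogen vs N/O acceptors that come within ``search_cutoff`` A of
    the donor in any frame."""
    top = trajectory.topology
    coords0 = trajectory.coordinates[0]
    heavies = [i for i, a in enumerate(top.atoms) if a.element in _POLAR_ELEMENTS]
    hydrogens = [i for i, a in enumerate(top.atoms) if a.element == "H"]
    donors: list[tuple[int, int]] = []
    for d in heavies:
        for h in hydrogens:
            if np.linalg.norm(coords0[h] - coords0[d]) < _COVALENT_DH:
                donors.append((d, h))
    min_dist = np.min(
        np.linalg.norm(
            trajectory.coordinates[:, :, None, :] - trajectory.coordinates[:, None, :, :], axis=-1
        ),
        axis=0,
    )
    pairs = []
    for d, h in donors:
        for acc in heavies:
            if acc == d:
                continue
            if min_dist[d, acc] <= search_cutoff:
                pairs.append((d, h, acc))
    return pairs
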