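"""Config-driven orchestration of the full analysis battery.

``run_pipeline`` validates every selection against the topology before
any stage runs, then executes the enabled stages in dependency order —
RMSD/RMSF, cross-correlation, PCA, hydrogen bonds, per-residue
energies, MM-PBSA — writing each stage's table to the output directory
as it completes.  A failing stage leaves earlier results on disk next
to a failure manifest naming the stage.

All literature thresholds (3.5 A / 120 deg hydrogen-bond criteria,
1.4 A probe, gamma/beta surface coefficients, dielectrics 1/80, 300 K)
are configuration defaults, never hard-coded in stage logic.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (
    cross_correlation_matrix,
    mode_displacement_profile,
    pca_from_trajectory,
    variance_fraction,
)
from .energy import per_residue_decomposition
from .fit import rmsd_series, rmsf_profile
from .hbonds import HBondCriteria, enumerate_candidate_pairs, hbond_occupancy
from .io import read_pdb, read_trajectory
from .mmpbsa import mmpbsa_single_trajectory
from .selection import select
from .solvation import SolvationParameters
from .structure import ForceFieldParameters, Structure, Trajectory

__all__ = ["PipelineConfig", "AnalysisReport", "StageError", "run_pipeline", "compare_systems", "write_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and its input provenance."""

    def __init__(self, stage: str, provenance: dict, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.provenance = provenance
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; loadable from a single JSON file."""

    topology_path: str | None = None
    trajectory_path: str | None = None
    parameters_path: str | None = None
    time_stride: float | None = None  # ps per frame, overrides file metadata

    #: named selections; ``calpha`` drives RMSD/RMSF/DCCM/PCA, ``ligand``
    #: drives H-bonds, energies and MM-PBSA.  Extra keys define residue
    #: panels (e.g. P loop 214-221) reported alongside.
    selections: dict[str, str] = field(
        default_factory=lambda: {"calpha": "name CA", "ligand": "resname LIG"}
    )

    run_rmsd: bool = True
    run_rmsf: bool = True
    run_dccm: bool = True
    run_pca: bool = True
    run_hbonds: bool = True
    run_energies: bool = True
    run_mmpbsa: bool = False  # PB per snapshot; enable deliberately

    superpose: bool = True
    hbond_max_distance: float = 3.5  # A (0.35 nm at the config boundary)
    hbond_min_angle_deg: float = 120.0
    hbond_pairs: list | None = None  # triplets of atom indices; None = auto
    pca_modes_reported: int = 20

    gamma: float = 0.00542
    beta: float = 0.92
    probe_radius: float = 1.4
    eps_in: float = 1.0
    eps_out: float = 80.0
    temperature: float = 300.0
    pb_spacing: float = 0.5
    snapshot_stride: int = 1
    entropy_stride: int | None = None

    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def solvation_parameters(self) -> SolvationParameters:
        return SolvationParameters(
            gamma=self.gamma,
            beta=self.beta,
            probe_radius=self.probe_radius,
            eps_in=self.eps_in,
            eps_out=self.eps_out,
        )

    def criteria(self) -> HBondCriteria:
        return HBondCriteria(
            max_distance=self.hbond_max_distance, min_angle_deg=self.hbond_min_angle_deg
        )

    def config_hash(self) -> str:
        # output_dir does not affect the analysis, so it is excluded:
        # re-running the same inputs anywhere yields the same hash
        payload = asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Tables from one pipeline run plus a provenance block."""

    rmsd: pd.DataFrame | None = None
    rmsf: pd.DataFrame | None = None
    dccm: pd.DataFrame | None = None
    pca_eigenvalues: pd.DataFrame | None = None
    pca_variance: pd.DataFrame | None = None
    pca_mode_profile: pd.DataFrame | None = None
    hbonds: pd.DataFrame | None = None
    residue_energies: pd.DataFrame | None = None
    mmpbsa: pd.DataFrame | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    _TABLES = (
        "rmsd",
        "rmsf",
        "dccm",
        "pca_eigenvalues",
        "pca_variance",
        "pca_mode_profile",
        "hbonds",
        "residue_energies",
        "mmpbsa",
    )


def _resolve_selections(topology: Structure, config: PipelineConfig) -> dict[str, np.ndarray]:
    resolved = {}
    for name, expr in config.selections.items():
        resolved[name] = select(topology, expr)
    for required in ("calpha",):
        if required not in resolved or resolved[required].size == 0:
            raise ValueError(f"selection {required!r} is missing or empty")
    return resolved


def run_pipeline(
    config: PipelineConfig,
    topology: Structure | None = None,
    trajectory: Trajectory | None = None,
) -> AnalysisReport:
    """Run the enabled stages and return (and optionally persist) the report.

    ``topology``/``trajectory`` may be passed in memory; otherwise they
    are loaded from the configured paths.  Selections are resolved and
    validated before any computation.
    """
    if topology is None:
        if config.topology_path is None:
            raise ValueError("no topology: set topology_path or pass one in memory")
        topology = read_pdb(config.topology_path)
        if config.parameters_path:
            p = Path(config.parameters_path)
            params = (
                ForceFieldParameters.from_json(p)
                if p.suffix == ".json"
                else ForceFieldParameters.from_csv(p)
            )
            topology = params.apply(topology)
    if trajectory is None:
        if config.trajectory_path is None:
            raise ValueError("no trajectory: set trajectory_path or pass one in memory")
        trajectory = read_trajectory(config.trajectory_path, topology, config.time_stride)
    if trajectory.topology is not topology:
        trajectory = Trajectory(trajectory.coordinates, trajectory.time_stride, topology)

    selections = _resolve_selections(topology, config)
    ca = selections["calpha"]
    ligand = selections.get("ligand", np.array([], dtype=int))

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(
        provenance={
            "config_hash": config.config_hash(),
            "mdpost_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "n_frames": trajectory.n_frames,
            "n_atoms": trajectory.n_atoms,
            "time_stride_ps": trajectory.time_stride,
            "stages": {},
        },
    )

    def run_stage(name: str, enabled: bool, fn) -> None:
        if not enabled:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            manifest = {
                "failed_stage": name,
                "error": str(exc),
                "completed_stages": list(report.provenance["stages"]),
            }
            if out_dir:
                (out_dir / "failure_manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(name, report.provenance, exc)
        report.provenance["stages"][name] = {
            "wall_time_s": round(time.perf_counter() - t0, 4)
        }
        if out_dir:
            _write_stage(report, name, out_dir)

    times = np.arange(trajectory.n_frames) * trajectory.time_stride

    def stage_rmsd():
        series = rmsd_series(trajectory, selection=ca)
        report.rmsd = pd.DataFrame({"frame_time_ps": times, "rmsd_A": series})

    def stage_rmsf():
        prof = rmsf_profile(trajectory, selection=ca, superpose=config.superpose)
        resids = [topology.atoms[i].residue_number for i in ca]
        report.rmsf = pd.DataFrame({"residue": resids, "rmsf_A": prof})

    def stage_dccm():
        m = cross_correlation_matrix(trajectory, ca, superpose=config.superpose)
        report.dccm = pd.DataFrame(m.values, index=m.labels, columns=m.labels)

    def stage_pca():
        pca = pca_from_trajectory(trajectory, ca, superpose=config.superpose)
        k_max = min(config.pca_modes_reported, pca.eigenvalues.size)
        report.pca_eigenvalues = pd.DataFrame(
            {"mode": np.arange(1, pca.eigenvalues.size + 1), "eigenvalue_A2": pca.eigenvalues}
        )
        report.pca_variance = pd.DataFrame(
            {
                "k": np.arange(1, k_max + 1),
                "cumulative_percent": [variance_fraction(pca, k) for k in range(1, k_max + 1)],
            }
        )
        profile = mode_displacement_profile(pca, 0)
        resids = [topology.atoms[i].residue_number for i in ca]
        report.pca_mode_profile = pd.DataFrame({"residue": resids, "pc1_displacement": profile})

    def stage_hbonds():
        pairs = config.hbond_pairs
        if pairs is None:
            pairs = enumerate_candidate_pairs(trajectory)
        pairs = [tuple(int(x) for x in p) for p in pairs]
        records = hbond_occupancy(trajectory, pairs, config.criteria())
        report.hbonds = pd.DataFrame(
            [
                {
                    "donor": r.donor,
                    "hydrogen": r.hydrogen,
                    "acceptor": r.acceptor,
                    "mean_distance_A": r.mean_distance,
                    "mean_angle_deg": r.mean_angle,
                    "probability_pct": r.probability,
                }
                for r in records
            ]
        )

    def stage_energies():
        if ligand.size == 0:
            raise ValueError("energies stage needs a non-empty 'ligand' selection")
        report.residue_energies = per_residue_decomposition(trajectory, ligand)

    def stage_mmpbsa():
        if ligand.size == 0:
            raise ValueError("MM-PBSA stage needs a non-empty 'ligand' selection")
        receptor = np.setdiff1d(np.arange(topology.n_atoms), ligand)
        result = mmpbsa_single_trajectory(
            trajectory,
            receptor,
            ligand,
            parameters=config.solvation_parameters(),
            snapshot_stride=config.snapshot_stride,
            entropy_stride=config.entropy_stride,
            pb_spacing=config.pb_spacing,
            temperature=config.temperature,
        )
        rows = [
            {"component": k, "kcal_mol": v, "stderr": result.standard_errors.get(k, 0.0)}
            for k, v in result.as_dict().items()
        ]
        report.mmpbsa = pd.DataFrame(rows)

    run_stage("rmsd", config.run_rmsd, stage_rmsd)
    run_stage("rmsf", config.run_rmsf, stage_rmsf)
    run_stage("dccm", config.run_dccm, stage_dccm)
    run_stage("pca_eigenvalues", config.run_pca, stage_pca)
    run_stage("hbonds", config.run_hbonds, stage_hbonds)
    run_stage("residue_energies", config.run_energies, stage_energies)
    run_stage("mmpbsa", config.run_mmpbsa, stage_mmpbsa)

    if out_dir:
        write_report(report, out_dir)
    return report


_INDEXED_TABLES = ("dccm", "residue_energies")


def _write_stage(report: AnalysisReport, name: str, directory: Path) -> None:
    names = (
        ("pca_eigenvalues", "pca_variance", "pca_mode_profile")
        if name == "pca_eigenvalues"
        else (name,)
    )
    for sub in names:
        table = getattr(report, sub, None)
        if table is not None:
            table.to_csv(directory / f"{sub}.csv", index=sub in _INDEXED_TABLES)


def write_report(report: AnalysisReport, directory: str | Path) -> None:
    """Persist every populated table as CSV plus provenance and a summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in AnalysisReport._TABLES:
        table = getattr(report, name)
        if table is not None:
            table.to_csv(directory / f"{name}.csv", index=name in _INDEXED_TABLES)
    (directory / "provenance.json").write_text(json.dumps(report.provenance, indent=1, default=str))
    lines = ["mdpost analysis report", "======================", ""]
    for name in AnalysisReport._TABLES:
        table = getattr(report, name)
        if table is None:
            continue
        lines.append(f"[{name}] {table.shape[0]} rows x {table.shape[1]} cols")
        if name == "mmpbsa":
            for _, row in table.iterrows():
                lines.append(f"  {row['component']:>16s} {row['kcal_mol']:10.3f} kcal/mol")
    lines.append("")
    lines.append(f"provenance: config {report.provenance.get('config_hash', '?')}, "
                 f"seed {report.provenance.get('seed', '?')}")
    (directory / "summary.txt").write_text("\n".join(lines) + "\n")


def compare_systems(report_a: AnalysisReport, report_b: AnalysisReport) -> dict[str, pd.DataFrame]:
    """Per-residue energy, occupancy and RMSF differences (A minus B).

    Requires identical residue panels in both reports; combined
    standard errors are added in quadrature.  Antisymmetric by
    construction: ``compare(A, B) == -compare(B, A)`` on every numeric
    column.
    """
    diffs: dict[str, pd.DataFrame] = {}
    if report_a.residue_energies is not None and report_b.residue_energies is not None:
        ea = report_a.residue_energies.reset_index()
        eb = report_b.residue_energies.reset_index()
        if ea["residue"].tolist() != eb["residue"].tolist():
            raise ValueError("panel mismatch: residue energy tables differ")
        out = pd.DataFrame({"residue": ea["residue"]})
        for c in ("elec_kcal_mol", "vdw_kcal_mol", "total_kcal_mol"):
            out[f"delta_{c}"] = (ea[c] - eb[c]).to_numpy()
            stem = c.rsplit("_kcal_mol", 1)[0]
            se = np.sqrt(ea[f"{stem}_stderr"] ** 2 + eb[f"{stem}_stderr"] ** 2)
            out[f"delta_{c}_stderr"] = se.to_numpy()
        diffs["residue_energies"] = out
    if report_a.hbonds is not None and report_b.hbonds is not None:
        ha, hb = report_a.hbonds, report_b.hbonds
        key_a = list(zip(ha["donor"], ha["hydrogen"], ha["acceptor"]))
        key_b = list(zip(hb["donor"], hb["hydrogen"], hb["acceptor"]))
        if key_a != key_b:
            raise ValueError("panel mismatch: hydrogen-bond pair lists differ")
        diffs["hbonds"] = pd.DataFrame(
            {
                "donor": ha["donor"],
                "acceptor": ha["acceptor"],
                "delta_probability_pct": (ha["probability_pct"] - hb["probability_pct"]).to_numpy(),
            }
        )
    if report_a.rmsf is not None and report_b.rmsf is not None:
        ra, rb = report_a.rmsf, report_b.rmsf
        if ra["residue"].tolist() != rb["residue"].tolist():
            raise ValueError("panel mismatch: RMSF residue lists differ")
        diffs["rmsf"] = pd.DataFrame(
            {"residue": ra["residue"], "delta_rmsf_A": (ra["rmsf_A"] - rb["rmsf_A"]).to_numpy()}
        )
    if not diffs:
        raise ValueError("reports share no comparable tables")
    return diffs
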