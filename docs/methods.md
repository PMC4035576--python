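# Methods

This note records the models implemented in `mdpost`, the parameters
that matter, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real trajectories.

## Units and constants

Coordinates are Ångström throughout (PDB native); thresholds quoted in
nm in the literature (e.g. the 0.35 nm hydrogen-bond distance) are
converted once at the configuration boundary. Energies are kcal/mol,
charges elementary charges, masses amu, temperatures K. Fixed
project-wide: k_B = 0.0019872 kcal/mol/K and the Coulomb prefactor
k = 332.0637 kcal·Å/(mol·e²).

## Superposition, RMSD, RMSF

Superposition is a weighted Kabsch fit with the reflection branch
excluded (det R = +1 enforced via the SVD sign correction); collinear
reference geometries are rejected because the rotation is
underdetermined. RMSD is measured against the first frame of the
analysed trajectory after fitting on the analysis selection. RMSF uses
a two-pass iterative mean (fit to frame 1 → mean → refit to the mean),
then `RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩`. Weights are equal by default;
mass-weighting is a flag. RMSF is per-Cα by default with an optional
per-residue average.

## Cross-correlation and PCA

The DCCM normalises the displacement inner products
`⟨Δr_i·Δr_j⟩` by the site fluctuations; entries are clipped to
[−1, 1] against rounding and the diagonal is set to exactly 1. The
positional covariance is unweighted (no masses appear in the defining
equations) and centred on the superposed trajectory mean. PCA uses a
symmetric eigendecomposition with eigenvalues sorted descending and a
deterministic sign convention (largest-magnitude eigenvector component
positive) so that mode plots are reproducible. The eigenvalue sum
equals the covariance trace by construction and is asserted to 1e-8
relative in tests. Mode-displacement profiles report the per-residue
Euclidean norm of an eigenvector's (x, y, z) triplet, optionally scaled
by √λ; unscaled is the default since either convention appears in the
literature.

Both operations accept `superpose=False` for ensembles generated in a
fixed laboratory frame. This matters for validation: the
Gaussian-network generator's analytic covariance retains
rotation-like displacement components that a Kabsch fit would partially
remove, so oracle comparisons are made without fitting, while real
trajectories (which drift and tumble) are analysed with fitting.

## Synthetic ensembles

The Gaussian network model (GNM) drives the fluctuation oracle: for a
contact graph with Kirchhoff matrix Γ, each Cartesian axis of each site
is displaced independently with covariance `(k_B T / k) Γ⁺`. GNM was
chosen over an anisotropic network because its covariance is exactly
analytic (one pseudo-inverse), and no anisotropy claim is tested.
Defaults — spring constant 1 kcal/mol/Å², 300 K, 7 Å contact cutoff,
10 ps frame stride — give site fluctuations of ~1 Å RMS, the magnitude
typical of a folded protein's Cα atoms at room temperature. A
disconnected contact graph is rejected (its covariance is undefined up
to rigid modes). Sampling uses `numpy.random.default_rng(seed)`;
identical seeds give identical trajectories.

The hydrogen-bond generator scripts exact geometries: the bonded
geometry must satisfy, and the broken geometry violate, the criteria,
and exactly `round(occupancy × n_frames)` frames are bonded with the
order shuffled by the seed — so recovered occupancies are exact by
construction, which is what makes them an oracle.

What the synthetic ensembles do **not** emulate: anharmonicity,
conformational substates, solvent damping, or correlated
rotation-translation coupling. Passing the recovery tests therefore
demonstrates the correctness of the estimators, not the realism of any
force field; applying the pipeline to a real trajectory remains subject
to the usual sampling-convergence caveats.

## Hydrogen bonds

Criteria: donor–acceptor distance < 3.5 Å and angle > 120°, both
configurable. The angle is evaluated at the hydrogen (D–H···A), the
convention under which near-linear bonds score 160–180°; a
donor-centred alternative (`angle_at="donor"`) is provided because the
phrase "acceptor…H-donor angle" is ambiguous, and the two conventions
genuinely classify bent geometries differently (tested). The hydrogen
must lie within 1.2 Å of the donor or the triplet is rejected.
Occupancy is `100·N_existence/N_total`; distance and angle means are
taken over bonded frames only and reported as NaN for never-bonded
pairs. Alternate bonds sharing a donor are evaluated independently —
no per-frame exclusivity is imposed, since the criteria themselves do
not imply any. Candidate pairs may be supplied explicitly or
auto-enumerated (N/O donors with an attached hydrogen against N/O
acceptors within 4 Å in any frame).

## Interaction energies

Intermolecular Coulomb and 12-6 Lennard-Jones sums with
Lorentz–Berthelot mixing, dielectric 1, **no cutoff and no periodic
images**: the decomposition targets bound-complex snapshots, where a
cutoff would break the exact additivity of the per-residue table
(asserted in tests: residue totals sum to the whole-protein ligand
energy to machine precision). Only intermolecular pairs are computed,
so 1–4 scaling never applies. Energies are gas-phase; solvent screening
enters only through the PB term of the MM-PBSA assembly.

## Poisson–Boltzmann solver

Linear PB at zero ionic strength (i.e. Poisson with a two-dielectric
boundary), discretised on a uniform grid with the standard 7-point
stencil. Choices:

* **Dielectric boundary** — the union of atomic spheres at their
  intrinsic radii; `inflate_probe=True` adds the 1.4 Å probe. The
  bare-radius default is what makes the Born-ion closed form
  `−k q²/2R (1/ε_in − 1/ε_out)` an exact oracle. This is simpler than a
  molecular (Connolly) surface and deviates from common MM-PBSA
  defaults in a direction that is system-dependent.
* **Link dielectrics** — each grid link's ε is the harmonic mean over
  four sample points along the link, which smooths the staircase
  boundary enough to give monotone convergence (Born-ion error 2.6% →
  0.7% → 0.15% at 0.8/0.4/0.2 Å spacing).
* **Charges** — trilinearly spread to the eight surrounding nodes.
* **Boundary condition** — Dirichlet, analytic Coulomb potential
  screened by ε_out on the box faces; the box extends 5 Å beyond the
  atomic spheres by default.
* **Linear solver** — the interior system is symmetric positive
  definite and is solved with Jacobi-preconditioned conjugate
  gradients (rtol 1e-10); non-convergence raises with the residual.
  CG replaces classical successive over-relaxation: same
  discretisation and solution, better robustness per iteration budget.
* **Self-energy cancellation** — the reported energy is
  `½Σq_i[φ_solv(x_i) − φ_ref(x_i)]·k`, where the reference solve uses
  the identical grid and charge spreading with ε_in everywhere, so the
  spacing-dependent grid self-energy cancels exactly; a zero-charge
  input returns exactly 0.

For binding, `polar_binding_component` solves complex, receptor and
ligand on one shared grid placement (single-trajectory protocol: the
species are coordinate subsets of the complex, which must partition
it). For two separated Born ions this term reproduces the analytic
screened-monopole law `k q₁q₂(1/ε_out − 1/ε_in)/d` to ~1% — note it
decays as 1/d and vanishes only at infinite separation; it is the
*total* electrostatics (Coulomb + reaction field) that is near zero for
distant charges.

## Nonpolar solvation and SASA

`ΔG_nonpol = γ·SAS + β` with γ = 0.00542 kcal/mol/Å², β = 0.92
kcal/mol. SASA is Shrake–Rupley with 960 sphere points by default
(min 96; 1% convergence and ≤0.5% rotation invariance verified),
probe 1.4 Å, delegated to biotite with per-atom radii passed
explicitly. In the binding difference the three β offsets leave a
constant −β; the tests that demand an exactly zero non-interacting
limit set β = 0 explicitly.

## Minimization and vibrational entropy

The entropy stage needs a differentiable potential; `ToyPotential`
provides harmonic bonds `E = k(r − r₀)²` (Amber-style force constant,
so the curvature at the minimum is 2k) plus optional intermolecular
Coulomb/LJ. Minimization is L-BFGS with analytic gradients until the
RMS gradient falls below 1e-4 kcal/mol/Å (the conventional end-state
tolerance); energy is non-increasing across accepted steps and a zero
step budget returns the input flagged unconverged.

The mass-weighted Hessian is built by central finite differences of
the analytic gradient (step 1e-4 Å) and symmetrised. Rigid-body modes
are removed by a relative eigenvalue threshold (1e-6 of the largest)
rather than a fixed count of six: a diatomic has five rigid modes, a
bent molecule six, and a complex of disconnected fragments more — the
threshold handles all three, and a genuinely negative eigenvalue
(saddle point) raises. Each surviving frequency contributes the quantum
harmonic-oscillator entropy `S = R[x/(eˣ−1) − ln(1−e⁻ˣ)]`,
x = hν/k_BT, evaluated at 300 K by default. Rotational and
translational entropy are omitted; in binding differences they cancel
only approximately, so reported −TΔS values carry that caveat. Without
a supplied potential the MM-PBSA driver reports −TΔS = 0, since
analysis trajectories carry no bonded topology.

## MM-PBSA assembly

Single-trajectory protocol throughout: receptor and ligand coordinates
are cut from complex frames, which forces all intramolecular terms to
cancel identically (asserted). MM, PB and SASA terms are averaged over
frames at `snapshot_stride`; the entropy term runs on its own sparser
`entropy_stride` after per-species minimization, mirroring the usual
practice of evaluating the expensive normal-mode term on fewer
snapshots. Standard errors are per-term standard errors of the frame
mean. `ΔG_bind` equals the sum of the five reported terms to 1e-9 by
construction.

## Structure preparation

Crystal-water filtering keeps a water iff any of its atoms lies within
the cutoff (default 4 Å) of any ligand atom; protein and ligand atoms
are never touched. Point mutation is purely geometric: ASP→ALA
truncates beyond Cβ and completes the methyl with ideal tetrahedral
hydrogens (C–H 1.09 Å); ASP→GLU inserts a CH₂ and rebuilds the
carboxylate with ideal bond lengths (C–C 1.52 Å, C–O 1.25 Å, O–C–O
126°). No rotamer search is performed — the grafted side chain
inherits the parent's orientation — and force-field parameters for new
atoms must be re-applied from a parameter table afterwards. Hydrogens
are expected in inputs used for hydrogen-bond and energy analyses;
geometry-only stages accept structures without them.

## Problem sizes used in the validation suite

Oracle recovery uses 2- and 20-site chains at 10⁵ frames (sampling
error ~1%, comfortably inside the 5% acceptance band), 50-atom toy
complexes for energy additivity, and 0.8/0.4/0.2 Å PB grids on a 2 Å
Born sphere. These sizes make the full suite and the acceptance script
run in seconds on one CPU while leaving each statistical check at
least a factor of three of headroom against its tolerance.

## Known limitations

* The PB solver is linear and salt-free; no Debye–Hückel screening.
* The dielectric boundary is a sphere union, not a molecular surface;
  absolute ΔG_pol values for real proteins would differ from
  Connolly-surface solvers.
* Mutation is geometric; clashes introduced by a graft are not
  relaxed (run the minimizer if needed).
* The toy potential is not a protein force field; entropy numbers for
  real systems require real bonded parameters.
* mmCIF, protonation-state prediction and PDB remediation are out of
  scope.
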