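# Methods

This note documents the models, numerical choices and limitations of the
`mlmm` package in enough detail to reproduce or criticize them.

## Units and constants

Energies in kcal/mol, lengths in Å, time in fs, masses in amu, charges in
elementary units. The two conversion constants are derived at import time
from CODATA values in `scipy.constants`, not hard-coded:

* 1 kcal/mol = 4.184e-4 amu·Å²/fs² (from 4184 J/mol and N_A);
* Coulomb constant k_e = e²/(4πε₀) = 332.0637 kcal·Å/(mol·e²);
* k_B = 1.98720e-3 kcal/(mol·K), so k_BT = 0.59616 kcal/mol at 300 K.

## Energy model

**Partition.** `E_total = E_ML + E_MM + E_ML-MM + E_kinetic`, validated on
every `EnergyReport` to 1e-10 relative.

**ML region.** Any object with `evaluate(elements, coords) → (energy,
forces)` satisfies the `MLPotentialContract`. The contract deliberately
exposes *only* the total: the free-energy scheme below never needs — and
never receives — a bonded/nonbonded split. The bundled surrogate is an
intramolecular force field (harmonic bonds/angles, cosine dihedrals,
LJ + Coulomb with 1-2/1-3 exclusions and AMBER-style 1-4 scaling ÷1.2 /
÷2.0) folded behind the contract. It is a stand-in with the right
*structure* (one opaque scalar), not an approximation of any trained model;
wrapping an ASE calculator or a TorchANI model requires only the one method.

**MM region.** Same functional forms, evaluated over the MM atoms only. LJ
parameters are stored per atom as self-pair A/B coefficients; heteropairs
use Lorentz–Berthelot combining on the recovered (σ, ε). Nonbonded pairs
closer than 1e-6 Å raise a singularity error rather than returning a huge
number.

**Coupling (mechanical embedding).** All ML×MM pairs interact through
Coulomb + 12-6 LJ. No exclusions cross the region boundary: the supported
use case is a whole-molecule ML region, so no covalent bond is ever cut and
no link atoms exist (cutting is rejected at `System` validation). No
long-range correction or cutoff is applied by default — the target systems
are small droplets; with a periodic box, the minimum-image convention is
used (orthorhombic boxes only).

**λ-coupling forms.** The λ schedule scales only the coupling:

* *linear*: `E(λ) = λ·E(1)`, `∂V/∂λ = E(1)`. Simple, but the integrand
  diverges at λ→0 in dense solvent (particles can overlap a vanishing
  solute).
* *soft-core* (default for TI): Beutler-style. LJ denominator `r⁶ →
  r⁶ + α(1−λ)σ⁶` with α = 0.5; Coulomb `r → sqrt(r² + β(1−λ))` with
  β = 1 Ų; both keep a linear λ prefactor. `E(0) = 0` exactly and `E(1)`
  equals the linear form exactly, so the endpoint states are
  form-independent; `∂V/∂λ` is analytic. Pairs with a repulsive-only LJ
  (B = 0) fall back to a 3 Å reference diameter for the soft-core shift —
  any positive shift removes the singularity without touching the
  endpoints. Whether Coulomb and LJ should be staged on separate legs is
  left to the protocol author; the default couples both with one λ.

Forces of every term are analytic and are tested against 5-point central
finite differences (relative error < 1e-6 at h = 1e-4 Å); `∂V/∂λ` is tested
against a central difference in λ.

## Dynamics

* **NVE**: velocity Verlet. Symplectic, so total energy shows a bounded
  oscillation whose amplitude scales as dt²; the suite verifies drift
  < 1e-5 (relative) over 10,000 steps at dt = 0.5 fs and the ~4× shrink on
  halving dt. Conservation is measured from an equilibrated, low-temperature
  (10 K Maxwell–Boltzmann after minimization, 1000-step pre-roll) start:
  starting at the exact minimum injects a one-time shadow-energy offset
  that the |E(t)−E(0)| metric would misread as drift, and the
  integrator-correctness question is independent of temperature.
* **NVT**: BAOAB-discretized Langevin with friction in 1/fs (default 0.05–0.1
  for sampling). At zero friction it reduces exactly to velocity Verlet.
  Identical seeds give bitwise-identical trajectories.
* **SHAKE**: classic iterative projection along previous-step bond vectors,
  applied to MM bonds containing exactly one hydrogen; tolerance 1e-8 Å,
  max 500 iterations (hard error on non-convergence), with the matching
  Δx/dt velocity correction. Default dt is 1 fs, 2 fs with SHAKE.
* **Rigid ML region** (`System.rigid_ml`): the region is propagated as a
  single translating body — net force distributed mass-proportionally, one
  shared velocity. Internal geometry is preserved to round-off, which is
  what makes the rigid-solute reduction of the free-energy scheme exact.
  Rigid-body *rotation* is deliberately not integrated; for the validation
  role of rigid solutes (identical conformers in both phases) only internal
  rigidity matters.
* **Minimization**: L-BFGS-B on the potential energy with analytic
  gradients; singular configurations encountered during line search return
  a large penalty so the search backtracks.
* Initial velocities are Maxwell–Boltzmann at the requested temperature
  with the center-of-mass motion removed, seeded.

Stability diagnostics report worst-case values over the trajectory: COM
velocity (total momentum / mass), translational energy ½M|v_COM|²,
rotational energy ½ωᵀIω with ω from the pseudo-inverse of the inertia
tensor, relative energy drift, and the total-energy standard deviation.

## Free-energy machinery

**Protocol.** Default: 11 evenly spaced λ windows on [0, 1], trapezoid
weights (w = {0.25, 0.5, 0.25} for {0, ½, 1}), soft-core coupling, 20%
equilibration discard. Gauss–Legendre nodes/weights and user-supplied
weights are alternatives; node/rule mismatches are errors.

**Statistics.** Window SEMs come from block averaging with ~√n blocks; the
implied statistical inefficiency g (sem² = g·var/n, clamped ≥ 1) is
reported per window. Quadrature uncertainty is √(Σ w_i² sem_i²), and the
coupling and reorganization uncertainties add in quadrature.

**Phases.** Water-phase windows propagate the full system at the window's
λ and record `∂V_coupling/∂λ` and `E_ML` per reported frame. The gas phase
is the ML region alone — same temperature, ML potential only, open
boundaries: the package takes the strict reading that the ML region is
described solely by its (surrogate) MLIP in both phases, so the intra-ML
term carries no λ dependence and its `∂V/∂λ` is identically zero.
`⟨E_ML⟩_water` is taken from the fully coupled (λ = 1) window, the physical
solvated ensemble. Sign conventions: `ΔG_reorg = ⟨E_ML⟩_water − ⟨E_ML⟩_gas`,
and λ 0→1 switches the coupling ON, so `ΔG_solvation` is the gas→water
transfer free energy. The assembly `ΔG_solvation = ΔG_coupling + ΔG_reorg`
is an exact identity of the estimator, enforced at construction.

**Oracles.** Three independent routes validate the sampled TI:

* *BAR*: the Bennett/maximum-likelihood equation solved by bracketed
  root-finding on forward (U₁−U₀ on state-0 samples) and reverse work,
  with the standard asymptotic variance from the Fermi-function moments;
  one-sided input degrades to exponential averaging; poor overlap warns
  rather than fails. Adjacent-window work is recomputed from stored frames,
  so the BAR route shares samples but not the TI estimator path.
* *Exact*: −kT·ln(Z₁/Z₀) by adaptive quadrature of the configurational
  integrals, for potentials with ≤ 2 degrees of freedom (absolute error
  well below 1e-6 kcal/mol for the harmonic test cases).
* *Closed form*: harmonic stiffness change k₀→k₁ gives
  (kT/2)·ln(k₁/k₀); with linear mixing the exact window average is
  kT(k₁−k₀)/(2k(λ)), evaluated by quadrature for the TI-vs-closed-form
  check.

No standard-state or volume corrections are applied anywhere.

A known, deliberate limitation: scaling the coupling leaves the
solute–solvent and intra-solute motions statistically coupled near λ = 1;
the reorganization correction compensates in the mean but does not remove
correlation effects between the two terms. The toy validations bound this
only statistically (TI vs BAR vs exact within combined errors).

## End-point analysis

* **RMSD**: Kabsch superposition (SVD with determinant correction) over a
  selection before the deviation; degenerate (collinear, < 3 atom) fits are
  errors. Fitting can be disabled for pre-aligned ensembles.
* **B-factors**: `B_i = (8π²/3)·⟨|r_i − ⟨r_i⟩|²⟩` after an iterative
  fit-to-mean superposition (two rounds). For synthetic ensembles generated
  in a common reference frame the superposition is skipped: fitting would
  absorb ~6 rigid-body degrees of freedom out of 3N and bias B low by a
  factor ≈ (1 − 2/N).
* **Generalized Born**: Still's pairwise formula with
  f_ij = sqrt(r² + R_iR_j·exp(−r²/4R_iR_j)), prefactor −½(1/ε_in − 1/ε_solv)k_e,
  which reduces exactly to the Born equation for one ion. Effective Born
  radii are the intrinsic (mbondi-flavoured) radii — no descreening
  integral. That is a real simplification: buried charges are
  under-screened relative to a proper GB; the quantitative anchor is the
  single-ion/closed-form regime, and relative trends only elsewhere.
* **Nonpolar**: γ·SASA with γ = 0.00542 kcal/mol/Ų and a fast approximate
  SASA (full solvent-expanded sphere area minus pairwise spherical-cap
  occlusions, clamped at zero; cap–cap overlaps ignored, so tightly packed
  atoms saturate at zero exposure).
* **Binding**: single-trajectory protocol, per frame
  ΔE = E(complex) − E(receptor) − E(ligand) for the Coulomb/LJ cross terms
  and the GB/nonpolar terms; ensemble mean ± SEM; no conformational-entropy
  term. The estimator is a method skeleton for ensemble-quality studies,
  not a calibrated affinity predictor.

## Synthetic fixtures

The generators define the study conditions; all are exactly reproducible
from (spec, seed).

* **Toy solute**: a connected chain of carbons (bond k = 300 kcal/mol/Ų,
  r₀ = 1.5 Å; angle k = 50, θ₀ = 109.5°; threefold dihedrals k = 0.3 for
  chains ≥ 4), LJ σ = 3.4 Å, ε = 0.1, Gaussian charges (σ_q = 0.15 e)
  shifted to sum exactly to zero. Stands in for a drug-sized ML region at
  desk scale (≤ ~12 atoms). The rigid variant freezes internal geometry via
  the rigid-body propagation above.
* **Solvent bath**: a *generic* bent triatomic (water-like geometry and
  charges; O σ = 3.1507 Å, ε = 0.1521; bond k = 200, angle k = 40) or a
  monatomic LJ fluid. Hydrogens carry a small guard LJ site (σ = 1 Å,
  ε = 0.05) because zero-LJ hydrogens make the Coulomb energy unbounded
  below — a deliberate departure from TIP3P, which this model does not
  claim to be. Molecules are placed by rejection sampling (≥ 1.5 Å between
  atoms of different molecules, optional spherical cavity for the solute);
  open-boundary droplets by default, optional periodic cube. The reference
  composition of 33 triatomic molecules gives 99 MM atoms around a small
  solute, mirroring a typical small solvated ML/MM benchmark system.
* **Harmonic ensembles**: i.i.d. isotropic Gaussian wobble about fixed
  means, no net rigid-body motion added — ground truth B = 8π²σ².
* **Harmonic 1D pairs**: endpoint potentials plus the analytic ΔG.

What the fixtures do *not* emulate: real chemistry (polarization, hydrogen
bonding anisotropy, conformational multi-modality), long-range
electrostatics, and MLIP inference noise. Passing tests therefore certify
the *estimators and integrators*, not force-field accuracy on real systems;
published benchmark numbers obtained with trained MLIPs (hydration-set
MAEs, protein–ligand RMSEs, inference-precision-limited NVE energy σ) are
out of reach of a surrogate by construction and are not targeted.

## Problem sizes used in the shipped validations

Chosen to exercise every code path at desk scale: 96-atom droplet
(6-atom solute + 30 triatomic molecules) for conservation; 40-atom system
(4-atom solute + 12 molecules), 9 soft-core windows × 2500 NVT steps for the
solvation TI and its BAR cross-check; 11 windows × 40,000 BAOAB steps for
the 1D sampled TI; 10⁶ steps for equipartition; 8000 frames × 60 atoms for
B-factor recovery.
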