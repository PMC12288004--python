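"""Molecular dynamics: velocity Verlet (NVE), BAOAB Langevin (NVT), SHAKE
constraints, energy minimization, and stability diagnostics.

Conventions: dt in fs, coordinates in A, velocities in A/fs, energies in
kcal/mol.  Forces (kcal/mol/A) are converted to accelerations with the
kcal/mol -> amu*A^2/fs^2 factor from :mod:`mlmm.units`.

The NVE integrator is symplectic, so the total energy shows a bounded
oscillation with no secular drift; halving dt shrinks the oscillation by
~4x, which the test suite uses as a convergence-order check.  With
``System.rigid_ml`` set, the ML region is propagated as a single translating
body (net force distributed mass-proportionally, one shared velocity), which
preserves its internal geometry to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .potentials import (
    EnergyReport,
    kinetic_energy,
    potential_energy_forces,
    total_forces,
)
from .system_model import Frame, System, Trajectory
from .units import BOLTZMANN_KCAL_MOL, INTERNAL_TO_KCAL_MOL, KCAL_MOL_TO_INTERNAL

__all__ = [
    "SimulationPlan",
    "StabilityReport",
    "apply_shake",
    "langevin_1d",
    "langevin_step",
    "maxwell_boltzmann_velocities",
    "minimize_frame",
    "run_simulation",
    "stability_diagnostics",
    "velocity_verlet_step",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters non-finite forces (blow-up)."""


@dataclass
class SimulationPlan:
    """Parameters of one MD run.

    ``init_temperature`` (K), when set, seeds Maxwell-Boltzmann velocities
    with the COM motion removed before the first step; otherwise the input
    frame's velocities are used as-is.
    """

    ensemble: str = "NVE"
    dt: float = 1.0
    n_steps: int = 1000
    temperature: float = 300.0
    friction: float = 0.01
    shake: bool = False
    shake_tolerance: float = 1.0e-8
    seed: int = 0
    report_interval: int = 10
    init_temperature: float | None = None

    def __post_init__(self) -> None:
        if self.ensemble not in ("NVE", "NVT"):
            raise ValueError(f"ensemble must be NVE or NVT, got {self.ensemble!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.ensemble == "NVT" and self.temperature <= 0:
            raise ValueError("NVT requires a positive temperature")


@dataclass
class StabilityReport:
    """Momentum/energy diagnostics over a trajectory (worst-case values)."""

    energy_drift: float
    energy_std: float
    com_velocity_norm: float
    translational_energy: float
    rotational_energy: float

    def __post_init__(self) -> None:
        for name in ("energy_drift", "energy_std", "com_velocity_norm",
                     "translational_energy", "rotational_energy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Force plumbing
# ---------------------------------------------------------------------------

def _accelerations(system: System, forces: np.ndarray, step: int | None = None) -> np.ndarray:
    if not np.all(np.isfinite(forces)):
        where = "" if step is None else f" at step {step}"
        raise IntegrationError(f"non-finite force encountered{where}; integration aborted")
    forces = _rigidize_forces(system, forces)
    return forces * KCAL_MOL_TO_INTERNAL / system.masses[:, None]


def _rigidize_forces(system: System, forces: np.ndarray) -> np.ndarray:
    """For a rigid ML region, distribute the net ML force mass-proportionally
    so that all ML atoms share one acceleration."""
    if not system.rigid_ml:
        return forces
    ml = system.ml_indices
    if ml.size == 0:
        return forces
    out = forces.copy()
    m = system.masses[ml]
    net = forces[ml].sum(axis=0)
    out[ml] = (m / m.sum())[:, None] * net
    return out


def _rigidize_velocities(system: System, velocities: np.ndarray) -> np.ndarray:
    if not system.rigid_ml:
        return velocities
    ml = system.ml_indices
    if ml.size == 0:
        return velocities
    out = velocities.copy()
    m = system.masses[ml][:, None]
    out[ml] = (m * velocities[ml]).sum(axis=0) / m.sum()
    return out


def maxwell_boltzmann_velocities(system: System, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Seeded Maxwell-Boltzmann draw (A/fs) with the COM motion removed."""
    kT_int = BOLTZMANN_KCAL_MOL * temperature * KCAL_MOL_TO_INTERNAL
    scale = np.sqrt(kT_int / system.masses)[:, None]
    v = rng.standard_normal((system.n_atoms, 3)) * scale
    m = system.masses[:, None]
    v -= (m * v).sum(axis=0) / m.sum()
    return _rigidize_velocities(system, v)


# ---------------------------------------------------------------------------
# Constraints (SHAKE)
# ---------------------------------------------------------------------------

def shake_constraints(system: System) -> list[tuple[int, int, float]]:
    """Constraint list: MM-region bonds involving exactly one hydrogen."""
    out = []
    for t in system.bonded_terms:
        if t.kind != "bond":
            continue
        i, j = t.atoms
        n_h = (system.atoms[i].element == "H") + (system.atoms[j].element == "H")
        if n_h == 1:
            out.append((i, j, t.equilibrium))
    return out


def apply_shake(system: System, frame_prev: Frame, frame_new: Frame,
                tolerance: float = 1.0e-8, max_iterations: int = 500,
                constraints: list[tuple[int, int, float]] | None = None) -> Frame:
    """Iteratively project ``frame_new`` onto the constraint manifold.

    Constrained bond lengths are restored to within ``tolerance`` (A) of their
    equilibrium values, using the previous-frame bond vectors as the
    correction directions (classic SHAKE).  Velocities receive the matching
    dx/dt correction when the two frames are separated in time.
    """
    if constraints is None:
        constraints = shake_constraints(system)
    if not constraints:
        return frame_new
    x = frame_new.coordinates.copy()
    v = frame_new.velocities.copy()
    xp = frame_prev.coordinates
    masses = system.masses
    dt = frame_new.time - frame_prev.time

    for _ in range(max_iterations):
        worst = 0.0
        for i, j, d in constraints:
            s = x[i] - x[j]
            dev = np.linalg.norm(s) - d
            worst = max(worst, abs(dev))
            if abs(dev) <= tolerance:
                continue
            rp = xp[i] - xp[j]
            denom = 2.0 * (s @ rp) * (1.0 / masses[i] + 1.0 / masses[j])
            if abs(denom) < 1e-14:
                raise RuntimeError(f"SHAKE: degenerate constraint geometry for pair ({i}, {j})")
            g = (d**2 - s @ s) / denom
            dxi = g * rp / masses[i]
            dxj = -g * rp / masses[j]
            x[i] += dxi
            x[j] += dxj
            if dt > 0:
                v[i] += dxi / dt
                v[j] += dxj / dt
        if worst <= tolerance:
            return Frame(x, v, frame_new.time)
    raise RuntimeError(
        f"SHAKE failed to converge in {max_iterations} iterations (worst residual {worst:.3e} A)"
    )


# ---------------------------------------------------------------------------
# Integrators
# ---------------------------------------------------------------------------

def velocity_verlet_step(system: System, frame: Frame, lam: float, dt: float,
                         form: str = "linear", forces: np.ndarray | None = None
                         ) -> Frame:
    """One symplectic velocity-Verlet step; time advances by dt."""
    if forces is None:
        forces, _ = total_forces(system, frame, lam, form)
    a = _accelerations(system, forces)
    v_half = frame.velocities + 0.5 * dt * a
    x_new = frame.coordinates + dt * v_half
    new = Frame(x_new, v_half, frame.time + dt)
    f_new, _ = total_forces(system, new, lam, form)
    new.velocities = v_half + 0.5 * dt * _accelerations(system, f_new)
    return new


def langevin_step(system: System, frame: Frame, lam: float, dt: float,
                  temperature: float, friction: float, rng: np.random.Generator,
                  form: str = "linear", forces: np.ndarray | None = None) -> Frame:
    """One BAOAB Langevin step (friction in 1/fs); deterministic given the rng
    state.  At friction = 0 this reduces exactly to velocity Verlet."""
    if forces is None:
        forces, _ = total_forces(system, frame, lam, form)
    a = _accelerations(system, forces)
    v = frame.velocities + 0.5 * dt * a
    x = frame.coordinates + 0.5 * dt * v
    if friction > 0:
        c1 = np.exp(-friction * dt)
        kT_int = BOLTZMANN_KCAL_MOL * temperature * KCAL_MOL_TO_INTERNAL
        sigma = np.sqrt((1.0 - c1 * c1) * kT_int / system.masses)[:, None]
        v = c1 * v + sigma * rng.standard_normal(v.shape)
        v = _rigidize_velocities(system, v)
    x = x + 0.5 * dt * v
    new = Frame(x, v, frame.time + dt)
    f_new, _ = total_forces(system, new, lam, form)
    new.velocities = v + 0.5 * dt * _accelerations(system, f_new)
    return new


def langevin_1d(force_fn, mass: float, x0: float, v0: float, dt: float,
                n_steps: int, temperature: float, friction: float,
                rng: np.random.Generator, sample_interval: int = 1
                ) -> tuple[np.ndarray, np.ndarray]:
    """Scalar BAOAB Langevin integrator for 1D model potentials.

    ``force_fn(x)`` returns the force in kcal/mol/A; mass in amu.  Returns
    (positions, velocities) sampled every ``sample_interval`` steps — a cheap
    sampler for the low-dimensional free-energy oracles and thermostat checks.
    """
    kT_int = BOLTZMANN_KCAL_MOL * temperature * KCAL_MOL_TO_INTERNAL
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT_int / mass)
    conv = KCAL_MOL_TO_INTERNAL / mass
    noise = rng.standard_normal(n_steps)
    xs = np.empty(n_steps // sample_interval)
    vs = np.empty_like(xs)
    x, v = float(x0), float(v0)
    a = force_fn(x) * conv
    k = 0
    for step in range(n_steps):
        v += 0.5 * dt * a
        x += 0.5 * dt * v
        v = c1 * v + c2 * noise[step]
        x += 0.5 * dt * v
        a = force_fn(x) * conv
        v += 0.5 * dt * a
        if (step + 1) % sample_interval == 0:
            xs[k] = x
            vs[k] = v
            k += 1
    return xs[:k], vs[:k]


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def minimize_frame(system: System, frame: Frame, lam: float = 1.0,
                   form: str = "linear", maxiter: int = 500) -> Frame:
    """Relax a configuration with L-BFGS on the potential energy."""
    from scipy.optimize import minimize

    shape = frame.coordinates.shape

    def fun(flat):
        from .potentials import SingularityError

        try:
            f = Frame(flat.reshape(shape), time=frame.time)
            forces, report = total_forces(system, f, lam, form)
        except SingularityError:
            # overshooting line-search step: return a penalty so it backtracks
            return 1e12, np.zeros_like(flat)
        return report.E_total - report.E_kinetic, -forces.ravel()

    res = minimize(fun, frame.coordinates.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return Frame(res.x.reshape(shape), frame.velocities.copy(), frame.time)


# ---------------------------------------------------------------------------
# Simulation driver and diagnostics
# ---------------------------------------------------------------------------

def run_simulation(system: System, frame0: Frame, plan: SimulationPlan,
                   lam: float = 1.0, form: str = "linear"
                   ) -> tuple[Trajectory, StabilityReport]:
    """Run MD per ``plan`` at fixed lambda; returns the reported trajectory
    (with per-frame energy reports) and a :class:`StabilityReport`."""
    rng = np.random.default_rng(plan.seed)
    frame = frame0.copy()
    if plan.init_temperature is not None:
        frame.velocities = maxwell_boltzmann_velocities(system, plan.init_temperature, rng)
    elif system.rigid_ml:
        frame.velocities = _rigidize_velocities(system, frame.velocities)

    constraints = shake_constraints(system) if plan.shake else []
    forces, report = total_forces(system, frame, lam, form)
    traj = Trajectory()
    traj.append(frame.copy(), report)
    dt = plan.dt
    kT_int = BOLTZMANN_KCAL_MOL * plan.temperature * KCAL_MOL_TO_INTERNAL
    c1 = np.exp(-plan.friction * dt) if plan.ensemble == "NVT" else 1.0
    sigma = np.sqrt(max(1.0 - c1 * c1, 0.0) * kT_int / system.masses)[:, None]

    # One potential evaluation per step: the end-of-step forces seed the next
    # step's initial half-kick.
    for step in range(plan.n_steps):
        prev = frame
        a = _accelerations(system, forces, step)
        v = frame.velocities + 0.5 * dt * a
        if plan.ensemble == "NVE":
            x = frame.coordinates + dt * v
        else:
            x = frame.coordinates + 0.5 * dt * v
            if plan.friction > 0:
                v = c1 * v + sigma * rng.standard_normal(v.shape)
                v = _rigidize_velocities(system, v)
            x = x + 0.5 * dt * v
        frame = Frame(x, v, prev.time + dt)
        if constraints:
            frame = apply_shake(system, prev, frame, plan.shake_tolerance,
                                constraints=constraints)
        forces, e_ml, e_mm, e_cpl = potential_energy_forces(system, frame, lam, form)
        frame.velocities = frame.velocities + 0.5 * dt * _accelerations(system, forces, step)
        if (step + 1) % plan.report_interval == 0:
            e_kin = kinetic_energy(system, frame)
            traj.append(frame.copy(), EnergyReport(
                E_ML=e_ml, E_MM=e_mm, E_coupling=e_cpl, E_kinetic=e_kin,
                E_total=e_ml + e_mm + e_cpl + e_kin, lam=lam, time=frame.time))

    return traj, stability_diagnostics(traj, system)


def stability_diagnostics(traj: Trajectory, system: System) -> StabilityReport:
    """Worst-case momentum/energy diagnostics over a trajectory.

    COM velocity is total momentum / total mass; translational energy is
    (1/2) M |v_COM|^2; rotational energy is (1/2) omega.T I omega from the
    angular momentum about the COM.  The drift is max |E(t) - E(0)| / |E(0)|
    over the reported total energies; maxima are reported for the momentum
    metrics.
    """
    if len(traj) < 1:
        raise ValueError("diagnostics require at least one frame")
    if any(f.velocities is None for f in traj):
        raise ValueError("diagnostics require velocities on every frame")
    m = system.masses
    M = m.sum()
    com_v, e_trans, e_rot = [], [], []
    for f in traj:
        p = (m[:, None] * f.velocities).sum(axis=0)
        v_com = p / M
        com_v.append(np.linalg.norm(v_com))
        e_trans.append(0.5 * M * v_com @ v_com * INTERNAL_TO_KCAL_MOL)
        com = (m[:, None] * f.coordinates).sum(axis=0) / M
        rel_x = f.coordinates - com
        rel_v = f.velocities - v_com
        L = (m[:, None] * np.cross(rel_x, rel_v)).sum(axis=0)
        r2 = np.einsum("ij,ij->i", rel_x, rel_x)
        inertia = (m[:, None, None] * (r2[:, None, None] * np.eye(3)[None]
                                       - rel_x[:, :, None] * rel_x[:, None, :])).sum(axis=0)
        omega = np.linalg.pinv(inertia, rcond=1e-10) @ L
        e_rot.append(max(0.5 * L @ omega, 0.0) * INTERNAL_TO_KCAL_MOL)

    if traj.energies:
        energies = np.array([r.E_total for r in traj.energies])
        e0 = energies[0]
        drift = float(np.max(np.abs(energies - e0)) / max(abs(e0), 1e-12))
        e_std = float(np.std(energies))
    else:
        drift, e_std = 0.0, 0.0
    return StabilityReport(
        energy_drift=drift,
        energy_std=e_std,
        com_velocity_norm=float(np.max(com_v)),
        translational_energy=float(np.max(e_trans)),
        rotational_energy=float(np.max(e_rot)),
    )
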