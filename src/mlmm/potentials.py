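"""Energy and force evaluation for ML/MM systems.

The total potential is partitioned as

    E_total = E_ML + E_MM + E_ML-MM(lambda)

where ``E_ML`` comes from the bound (indivisible) ML potential, ``E_MM`` is a
classical force field over the MM region, and the region-region coupling
``E_ML-MM`` is a mechanical-embedding sum of Coulomb and 12-6 Lennard-Jones
pair terms, scaled by the alchemical parameter lambda.

Two coupling forms are provided:

* ``linear`` — E(lambda) = lambda * E(1); simplest, but the integrand
  diverges at the decoupled endpoint in dense solvent.
* ``softcore`` — Beutler-style: the LJ denominator r^6 is shifted by
  alpha*(1-lambda)*sigma^6 (alpha = 0.5) and the Coulomb denominator r is
  replaced by sqrt(r^2 + beta*(1-lambda)) (beta = 1 A^2), with a linear
  lambda prefactor on both.  E(0) = 0 exactly and E(1) matches the linear
  form exactly, so endpoint states are form-independent.

All evaluators return analytic forces; dV/dlambda is analytic as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .system_model import (
    Atom,
    BondedTerm,
    Frame,
    System,
    _normalize_pair,
    auto_exclusions,
)
from .units import COULOMB_CONSTANT, INTERNAL_TO_KCAL_MOL

__all__ = [
    "EnergyReport",
    "SurrogateMLParams",
    "SurrogateMLPotential",
    "coupling_energy_forces",
    "kinetic_energy",
    "mm_energy_forces",
    "surrogate_ml_energy_forces",
    "total_energy_report",
    "total_forces",
]

_SINGULARITY_R = 1.0e-6          # A; closer nonbonded pairs are a hard error
_SOFTCORE_ALPHA_LJ = 0.5         # dimensionless shift on sigma^6
_SOFTCORE_BETA_COUL = 1.0        # A^2 shift under the Coulomb square root
_FALLBACK_SIGMA6 = 3.0**6        # A^6 reference for repulsion-only softcore pairs


class SingularityError(ValueError):
    """A nonbonded pair collapsed below the distance floor."""


@dataclass
class EnergyReport:
    """Per-configuration energy decomposition (kcal/mol) at a given lambda."""

    E_ML: float
    E_MM: float
    E_coupling: float
    E_kinetic: float
    E_total: float
    lam: float = 1.0
    time: float = 0.0

    def __post_init__(self) -> None:
        total = self.E_ML + self.E_MM + self.E_coupling + self.E_kinetic
        scale = max(abs(total), abs(self.E_total), 1.0)
        if abs(total - self.E_total) > 1.0e-10 * scale:
            raise ValueError(
                f"energy report inconsistent: components sum to {total}, E_total={self.E_total}"
            )


# ---------------------------------------------------------------------------
# Pairwise helpers
# ---------------------------------------------------------------------------

def _min_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        disp = disp - box * np.round(disp / box)
    return disp


def _pair_geometry(coords, idx_i, idx_j, box):
    disp = _min_image(coords[idx_i] - coords[idx_j], box)
    r = np.linalg.norm(disp, axis=1)
    if r.size and r.min() < _SINGULARITY_R:
        a = int(np.argmin(r))
        raise SingularityError(
            f"atoms {int(idx_i[a])} and {int(idx_j[a])} overlap (r = {r[a]:.2e} A)"
        )
    return disp, r


def _combine_lj(sig_i, eps_i, sig_j, eps_j):
    """Lorentz-Berthelot combining to pair (A, B) coefficients."""
    sigma = 0.5 * (sig_i + sig_j)
    eps = np.sqrt(eps_i * eps_j)
    s6 = sigma**6
    return 4.0 * eps * s6 * s6, 4.0 * eps * s6


def _nonbonded_pair_table(atoms: Sequence[Atom], indices: np.ndarray,
                          exclusions: set, pairs14: set,
                          scale_c14: float, scale_lj14: float) -> dict:
    """Precompute index/parameter arrays for all interacting pairs within
    ``indices`` (exclusions removed, 1-4 pairs scaled)."""
    sig = np.empty(len(atoms))
    eps = np.empty(len(atoms))
    for a in atoms:
        sig[a.index], eps[a.index] = a.sigma_epsilon
    charges = np.array([a.charge for a in atoms])

    ii, jj = np.triu_indices(len(indices), k=1)
    gi, gj = indices[ii], indices[jj]
    keep, cscale, ljscale = [], [], []
    for a, b in zip(gi, gj):
        pair = _normalize_pair(int(a), int(b))
        if pair in exclusions:
            keep.append(False)
            cscale.append(0.0)
            ljscale.append(0.0)
        elif pair in pairs14:
            keep.append(True)
            cscale.append(scale_c14)
            ljscale.append(scale_lj14)
        else:
            keep.append(True)
            cscale.append(1.0)
            ljscale.append(1.0)
    keep = np.array(keep, dtype=bool)
    gi, gj = gi[keep], gj[keep]
    cscale = np.array(cscale)[keep]
    ljscale = np.array(ljscale)[keep]
    A, B = _combine_lj(sig[gi], eps[gi], sig[gj], eps[gj])
    return {
        "i": gi, "j": gj,
        "qq": COULOMB_CONSTANT * charges[gi] * charges[gj] * cscale,
        "A": A * ljscale, "B": B * ljscale,
    }


def _cross_pair_table(atoms: Sequence[Atom], ml_idx: np.ndarray, mm_idx: np.ndarray) -> dict:
    """All ML x MM pairs; no exclusions cross the region boundary."""
    sig = np.empty(len(atoms))
    eps = np.empty(len(atoms))
    for a in atoms:
        sig[a.index], eps[a.index] = a.sigma_epsilon
    charges = np.array([a.charge for a in atoms])
    gi = np.repeat(ml_idx, len(mm_idx))
    gj = np.tile(mm_idx, len(ml_idx))
    A, B = _combine_lj(sig[gi], eps[gi], sig[gj], eps[gj])
    return {"i": gi, "j": gj, "qq": COULOMB_CONSTANT * charges[gi] * charges[gj],
            "A": A, "B": B}


def _plain_nonbonded(table, coords, box, forces):
    """Unscaled Coulomb + LJ over a pair table; accumulates forces, returns E."""
    if table["i"].size == 0:
        return 0.0
    disp, r = _pair_geometry(coords, table["i"], table["j"], box)
    inv_r = 1.0 / r
    inv_r6 = inv_r**6
    e_coul = table["qq"] * inv_r
    e_lj = table["A"] * inv_r6**2 - table["B"] * inv_r6
    # dU/dr terms
    dU = -e_coul * inv_r + (-12.0 * table["A"] * inv_r6**2 + 6.0 * table["B"] * inv_r6) * inv_r
    fvec = -(dU * inv_r)[:, None] * disp
    np.add.at(forces, table["i"], fvec)
    np.add.at(forces, table["j"], -fvec)
    return float(e_coul.sum() + e_lj.sum())


# ---------------------------------------------------------------------------
# Bonded kernels (shared by the MM force field and the surrogate ML potential)
# ---------------------------------------------------------------------------

def _bond_energy_forces(terms, coords, box, forces):
    if not terms:
        return 0.0
    i = np.array([t.atoms[0] for t in terms])
    j = np.array([t.atoms[1] for t in terms])
    k = np.array([t.force_constant for t in terms])
    r0 = np.array([t.equilibrium for t in terms])
    disp = _min_image(coords[i] - coords[j], box)
    r = np.linalg.norm(disp, axis=1)
    delta = r - r0
    energy = 0.5 * k * delta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        fmag = np.where(r > 1e-12, -k * delta / r, 0.0)
    fvec = fmag[:, None] * disp
    np.add.at(forces, i, fvec)
    np.add.at(forces, j, -fvec)
    return float(energy.sum())


def _angle_energy_forces(terms, coords, box, forces):
    if not terms:
        return 0.0
    i = np.array([t.atoms[0] for t in terms])
    j = np.array([t.atoms[1] for t in terms])  # central atom
    l = np.array([t.atoms[2] for t in terms])
    k = np.array([t.force_constant for t in terms])
    t0 = np.array([t.equilibrium for t in terms])
    u = _min_image(coords[i] - coords[j], box)
    v = _min_image(coords[l] - coords[j], box)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
    dE = k * (theta - t0)
    # dtheta/dri and dtheta/drl
    uhat = u / nu[:, None]
    vhat = v / nv[:, None]
    dth_di = (cos_t[:, None] * uhat - vhat) / (nu * sin_t)[:, None]
    dth_dl = (cos_t[:, None] * vhat - uhat) / (nv * sin_t)[:, None]
    f_i = -dE[:, None] * dth_di
    f_l = -dE[:, None] * dth_dl
    np.add.at(forces, i, f_i)
    np.add.at(forces, l, f_l)
    np.add.at(forces, j, -(f_i + f_l))
    return float((0.5 * k * (theta - t0) ** 2).sum())


def _dihedral_energy_forces(terms, coords, box, forces):
    if not terms:
        return 0.0
    energy = 0.0
    for t in terms:
        ia, ib, ic, id_ = t.atoms
        r_ij = _min_image(coords[ia] - coords[ib], box)
        r_kj = _min_image(coords[ic] - coords[ib], box)
        r_kl = _min_image(coords[ic] - coords[id_], box)
        m = np.cross(r_ij, r_kj)
        n = np.cross(r_kj, r_kl)
        nrkj = np.linalg.norm(r_kj)
        phi = np.arctan2((r_ij @ n) * nrkj, m @ n)
        energy += t.force_constant * (1.0 + np.cos(t.periodicity * phi - t.phase))
        dE_dphi = -t.force_constant * t.periodicity * np.sin(t.periodicity * phi - t.phase)
        m2 = m @ m
        n2 = n @ n
        if m2 < 1e-16 or n2 < 1e-16:
            continue  # collinear: torsion undefined, force taken as zero
        f_i = -dE_dphi * (nrkj / m2) * m
        f_l = dE_dphi * (nrkj / n2) * n
        p = (r_ij @ r_kj) / nrkj**2
        q = (r_kl @ r_kj) / nrkj**2
        sv = p * f_i - q * f_l
        forces[ia] += f_i
        forces[ib] += sv - f_i
        forces[ic] += -sv - f_l
        forces[id_] += f_l
    return float(energy)


def _bonded_energy_forces(terms: Sequence[BondedTerm], coords, box, forces):
    by_kind = {"bond": [], "angle": [], "dihedral": []}
    for t in terms:
        by_kind[t.kind].append(t)
    e = _bond_energy_forces(by_kind["bond"], coords, box, forces)
    e += _angle_energy_forces(by_kind["angle"], coords, box, forces)
    e += _dihedral_energy_forces(by_kind["dihedral"], coords, box, forces)
    return e


# ---------------------------------------------------------------------------
# MM force field
# ---------------------------------------------------------------------------

def _mm_pair_table(system: System) -> dict:
    if "mm_pairs" not in system._cache:
        system._cache["mm_pairs"] = _nonbonded_pair_table(
            system.atoms, system.mm_indices, system.exclusions, system.pairs14,
            system.scale14_coulomb, system.scale14_lj,
        )
    return system._cache["mm_pairs"]


def mm_energy_forces(system: System, frame: Frame) -> tuple[float, np.ndarray]:
    """Classical force-field energy of the MM region.

    E = bonds + angles + dihedrals + intra-MM LJ + intra-MM Coulomb, with
    exclusions honored and 1-4 pairs scaled.  Returns (energy in kcal/mol,
    per-atom forces in kcal/mol/A over the full atom array; ML rows are zero).
    """
    coords = frame.coordinates
    forces = np.zeros_like(coords)
    energy = _bonded_energy_forces(system.bonded_terms, coords, system.box, forces)
    energy += _plain_nonbonded(_mm_pair_table(system), coords, system.box, forces)
    return energy, forces


# ---------------------------------------------------------------------------
# Surrogate ML potential
# ---------------------------------------------------------------------------

@dataclass
class SurrogateMLParams:
    """Parameters of the surrogate "ML" potential over the ML-region atoms.

    Internally this is an ordinary intramolecular force field (harmonic
    bonds/angles, cosine dihedrals, LJ + Coulomb with the usual exclusions),
    but it is exposed *only* through :class:`SurrogateMLPotential`, which
    returns a single total energy with no component breakdown — mimicking the
    indivisibility of a trained ML interatomic potential.  Atom indices here
    are local to the ML region (0..n_ml-1).
    """

    elements: list[str]
    charges: np.ndarray
    lj_A: np.ndarray
    lj_B: np.ndarray
    bonded_terms: list[BondedTerm] = field(default_factory=list)
    exclusions: set = field(default_factory=set)
    pairs14: set = field(default_factory=set)
    scale14_coulomb: float = 1.0 / 1.2
    scale14_lj: float = 0.5

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_A = np.asarray(self.lj_A, dtype=float)
        self.lj_B = np.asarray(self.lj_B, dtype=float)
        n = len(self.elements)
        if not (len(self.charges) == len(self.lj_A) == len(self.lj_B) == n):
            raise ValueError("surrogate parameter arrays must match the element count")
        for t in self.bonded_terms:
            if any(a >= n for a in t.atoms):
                raise ValueError(f"surrogate term {t.kind}{t.atoms} out of range for {n} atoms")

    @classmethod
    def from_topology(cls, section: dict, atoms: Sequence[Atom], ml_global: list[int]
                      ) -> "SurrogateMLParams":
        """Build from a topology ``ml_potential`` section (global indices)."""
        from .system_model import _bonded_from_records  # shared record parsing

        local = {g: i for i, g in enumerate(ml_global)}

        def _localize(terms):
            out = []
            for t in terms:
                if any(a not in local for a in t.atoms):
                    raise ValueError(
                        f"ml_potential term {t.kind}{t.atoms} references non-ML atoms"
                    )
                out.append(BondedTerm(t.kind, tuple(local[a] for a in t.atoms),
                                      t.force_constant, t.equilibrium, t.periodicity, t.phase))
            return out

        bonds = _localize(_bonded_from_records(section.get("bonds"), "bond"))
        angles = _localize(_bonded_from_records(section.get("angles"), "angle"))
        dihedrals = _localize(_bonded_from_records(section.get("dihedrals"), "dihedral"))
        excluded, scaled = auto_exclusions(len(ml_global), bonds)
        ml_atoms = [atoms[g] for g in ml_global]
        return cls(
            elements=[a.element for a in ml_atoms],
            charges=np.array([a.charge for a in ml_atoms]),
            lj_A=np.array([a.lj_A for a in ml_atoms]),
            lj_B=np.array([a.lj_B for a in ml_atoms]),
            bonded_terms=bonds + angles + dihedrals,
            exclusions=excluded,
            pairs14=scaled,
        )

    def build(self) -> "SurrogateMLPotential":
        return SurrogateMLPotential(self)


def surrogate_ml_energy_forces(params: SurrogateMLParams, elements: Sequence[str],
                               coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Evaluate the surrogate potential: one scalar energy + forces.

    ``elements`` must match the parameterized element sequence — the same
    identity check a trained MLIP would perform on its input species.
    """
    if list(elements) != list(params.elements):
        raise ValueError(
            f"element mismatch: surrogate parameterized for {params.elements}, got {list(elements)}"
        )
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(params.elements), 3):
        raise ValueError(f"coordinates must have shape ({len(params.elements)}, 3)")
    forces = np.zeros_like(coords)
    energy = _bonded_energy_forces(params.bonded_terms, coords, None, forces)
    key = "_pair_table"
    table = getattr(params, key, None)
    if table is None:
        pseudo = [Atom(i, el, 1.0, q, a, b, "MM") for i, (el, q, a, b) in
                  enumerate(zip(params.elements, params.charges, params.lj_A, params.lj_B))]
        table = _nonbonded_pair_table(pseudo, np.arange(len(pseudo)), params.exclusions,
                                      params.pairs14, params.scale14_coulomb, params.scale14_lj)
        object.__setattr__(params, key, table)
    energy += _plain_nonbonded(table, coords, None, forces)
    return energy, forces


class SurrogateMLPotential:
    """An :class:`MLPotentialContract` implementation backed by
    :class:`SurrogateMLParams`; exposes only the indivisible total."""

    def __init__(self, params: SurrogateMLParams):
        self.params = params
        self.n_atoms = len(params.elements)
        self.elements = list(params.elements)

    def evaluate(self, elements, coordinates):
        return surrogate_ml_energy_forces(self.params, elements, coordinates)


# ---------------------------------------------------------------------------
# ML-MM coupling
# ---------------------------------------------------------------------------

def _coupling_table(system: System) -> dict:
    if "coupling_pairs" not in system._cache:
        system._cache["coupling_pairs"] = _cross_pair_table(
            system.atoms, system.ml_indices, system.mm_indices
        )
    return system._cache["coupling_pairs"]


def coupling_energy_forces(system: System, frame: Frame, lam: float,
                           form: str = "linear") -> tuple[float, np.ndarray, float]:
    """Lambda-scaled nonbonded ML-MM coupling.

    Returns (energy, per-atom forces, dV/dlambda), all analytic.  ``form`` is
    ``"linear"`` or ``"softcore"``; the two agree exactly at both endpoints.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if form not in ("linear", "softcore"):
        raise ValueError(f"unknown coupling form {form!r}")
    table = _coupling_table(system)
    coords = frame.coordinates
    forces = np.zeros_like(coords)
    if table["i"].size == 0:
        return 0.0, forces, 0.0
    disp, r = _pair_geometry(coords, table["i"], table["j"], system.box)
    qq, A, B = table["qq"], table["A"], table["B"]

    if form == "linear" or lam == 1.0:
        inv_r = 1.0 / r
        inv_r6 = inv_r**6
        e1 = qq * inv_r + A * inv_r6**2 - B * inv_r6
        dU1 = -qq * inv_r**2 + (-12.0 * A * inv_r6**2 + 6.0 * B * inv_r6) * inv_r
        dvdl = float(e1.sum())
        if form == "softcore" and lam == 1.0:
            # endpoint value is form-independent; dV/dlambda is not
            dvdl = _softcore_dvdl(qq, A, B, r, lam)
        energy = lam * float(e1.sum())
        fvec = -(lam * dU1 / r)[:, None] * disp
    else:
        s6 = np.where((A > 0) & (B > 0), np.divide(A, np.where(B > 0, B, 1.0)),
                      np.where(A + B > 0, _FALLBACK_SIGMA6, 0.0))
        Dc = r**2 + _SOFTCORE_BETA_COUL * (1.0 - lam)
        Dl = r**6 + _SOFTCORE_ALPHA_LJ * (1.0 - lam) * s6
        inv_sqrt_Dc = 1.0 / np.sqrt(Dc)
        with np.errstate(divide="ignore", invalid="ignore"):
            invDl = np.where(Dl > 0, 1.0 / Dl, 0.0)
        e_c = lam * qq * inv_sqrt_Dc
        e_l = lam * (A * invDl**2 - B * invDl)
        energy = float(e_c.sum() + e_l.sum())
        dvdl = _softcore_dvdl(qq, A, B, r, lam, s6=s6)
        # dU/dr
        dU = (-lam * qq * r * inv_sqrt_Dc**3
              + lam * (-2.0 * A * invDl**3 + B * invDl**2) * 6.0 * r**5)
        fvec = -(dU / r)[:, None] * disp

    np.add.at(forces, table["i"], fvec)
    np.add.at(forces, table["j"], -fvec)
    return float(energy), forces, float(dvdl)


def _softcore_dvdl(qq, A, B, r, lam, s6=None):
    if s6 is None:
        s6 = np.where((A > 0) & (B > 0), np.divide(A, np.where(B > 0, B, 1.0)),
                      np.where(A + B > 0, _FALLBACK_SIGMA6, 0.0))
    Dc = r**2 + _SOFTCORE_BETA_COUL * (1.0 - lam)
    Dl = r**6 + _SOFTCORE_ALPHA_LJ * (1.0 - lam) * s6
    inv_sqrt_Dc = 1.0 / np.sqrt(Dc)
    with np.errstate(divide="ignore", invalid="ignore"):
        invDl = np.where(Dl > 0, 1.0 / Dl, 0.0)
    d_c = qq * inv_sqrt_Dc + lam * qq * (_SOFTCORE_BETA_COUL / 2.0) * inv_sqrt_Dc**3
    d_l = (A * invDl**2 - B * invDl) \
        + lam * (2.0 * A * invDl**3 - B * invDl**2) * _SOFTCORE_ALPHA_LJ * s6
    return float(d_c.sum() + d_l.sum())


# ---------------------------------------------------------------------------
# Totals
# ---------------------------------------------------------------------------

def kinetic_energy(system: System, frame: Frame) -> float:
    """Sum 1/2 m v^2 over all atoms, converted to kcal/mol."""
    v2 = np.einsum("ij,ij->i", frame.velocities, frame.velocities)
    return float(0.5 * np.dot(system.masses, v2) * INTERNAL_TO_KCAL_MOL)


def ml_energy_forces(system: System, frame: Frame) -> tuple[float, np.ndarray]:
    """Evaluate the bound ML potential on the ML-region coordinates; forces
    are scattered back into the full atom array."""
    forces = np.zeros_like(frame.coordinates)
    ml = system.ml_indices
    if ml.size == 0 or system.ml_potential is None:
        return 0.0, forces
    e, f = system.ml_potential.evaluate(system.ml_elements(), frame.coordinates[ml])
    forces[ml] = f
    return float(e), forces


def potential_energy_forces(system: System, frame: Frame, lam: float = 1.0,
                            form: str = "linear"
                            ) -> tuple[np.ndarray, float, float, float]:
    """Potential-only evaluation: (forces, E_ML, E_MM, E_coupling)."""
    e_mm, f_mm = mm_energy_forces(system, frame)
    e_ml, f_ml = ml_energy_forces(system, frame)
    e_cpl, f_cpl, _ = coupling_energy_forces(system, frame, lam, form)
    return f_mm + f_ml + f_cpl, e_ml, e_mm, e_cpl


def total_forces(system: System, frame: Frame, lam: float = 1.0,
                 form: str = "linear") -> tuple[np.ndarray, EnergyReport]:
    """Total forces plus the corresponding :class:`EnergyReport`."""
    forces, e_ml, e_mm, e_cpl = potential_energy_forces(system, frame, lam, form)
    e_kin = kinetic_energy(system, frame)
    report = EnergyReport(E_ML=e_ml, E_MM=e_mm, E_coupling=e_cpl, E_kinetic=e_kin,
                          E_total=e_ml + e_mm + e_cpl + e_kin, lam=lam, time=frame.time)
    return forces, report


def total_energy_report(system: System, frame: Frame, lam: float = 1.0,
                        form: str = "linear") -> EnergyReport:
    """Energy decomposition at the given lambda (components + kinetic)."""
    return total_forces(system, frame, lam, form)[1]
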