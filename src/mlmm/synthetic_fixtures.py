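"""Seeded generators for toy systems with known answers.

Everything the test suite and the validation oracles consume is generated
here: flexible/rigid chain solutes described by a surrogate ML potential,
triatomic or monatomic solvent baths, harmonic ensembles with closed-form
B-factors, and paired 1D potentials with analytic free-energy differences.
Identical spec + seed always reproduces identical output.

The triatomic solvent is a *generic* bent LJ + point-charge model — water-like
geometry and charges, deliberately softer bonds than TIP3P — not a claim of
fidelity to any published water model.  Its parameters are plain module data
and may be edited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .potentials import SurrogateMLParams
from .system_model import Atom, BondedTerm, Frame, System, Trajectory, auto_exclusions
from .units import kT as thermal_energy

__all__ = [
    "FixtureSpec",
    "Harmonic1D",
    "PackingError",
    "TRIATOMIC_SOLVENT",
    "combine_solute_bath",
    "make_harmonic_1d",
    "make_harmonic_ensemble",
    "make_solvent_bath",
    "make_toy_solute",
]

#: Generic bent triatomic solvent (O-H-H pattern): per-molecule neutral,
#: water-like geometry, moderately stiff bonds.  Editable data, not TIP3P.
#: The hydrogens carry a small guard LJ site so that bare charges can never
#: collapse onto them (zero-LJ hydrogens make the Coulomb energy unbounded).
TRIATOMIC_SOLVENT = {
    "elements": ["O", "H", "H"],
    "charges": [-0.834, 0.417, 0.417],
    "sigma": [3.1507, 1.0, 1.0],
    "epsilon": [0.1521, 0.05, 0.05],
    "bond_k": 200.0,          # kcal/mol/A^2
    "bond_r0": 0.9572,        # A
    "angle_k": 40.0,          # kcal/mol/rad^2
    "angle_theta0": math.radians(104.52),
}

#: Monatomic LJ solvent (argon-like).
MONATOMIC_SOLVENT = {"element": "Ar", "sigma": 3.4, "epsilon": 0.238, "charge": 0.0}


class PackingError(RuntimeError):
    """Solvent placement failed to satisfy the distance constraints."""


@dataclass
class FixtureSpec:
    """Declarative fixture request (used by the make-fixture CLI)."""

    kind: str
    n_atoms: int = 6
    n_molecules: int = 33
    box_edge: float = 12.0
    model: str = "lj_charge_triatomic"
    flexible: bool = True
    variance: float = 0.1
    n_frames: int = 1000
    k0: float = 1.0
    k1: float = 4.0
    temperature: float = 300.0
    seed: int = 0


# ---------------------------------------------------------------------------
# Toy solute
# ---------------------------------------------------------------------------

_SOLUTE_BOND_K = 300.0
_SOLUTE_BOND_R0 = 1.5
_SOLUTE_ANGLE_K = 50.0
_SOLUTE_ANGLE_T0 = math.radians(109.5)
_SOLUTE_DIHEDRAL_K = 0.3
_SOLUTE_SIGMA = 3.4
_SOLUTE_EPSILON = 0.1
_SOLUTE_CHARGE_SCALE = 0.15


def make_toy_solute(n_atoms: int, flexible: bool = True, seed: int = 0
                    ) -> tuple[System, SurrogateMLParams, Frame]:
    """A connected carbon chain forming the ML region of a hybrid system.

    Charges are drawn at random and shifted to sum exactly to zero; bonds,
    angles and (for chains of four or more atoms) threefold dihedrals are
    folded into the surrogate ML potential.  ``flexible=False`` marks the
    region rigid: dynamics then preserves its internal geometry exactly.
    """
    if n_atoms < 2:
        raise ValueError(f"a chain solute needs at least two atoms, got {n_atoms}")
    rng = np.random.default_rng(seed)

    charges = rng.normal(0.0, _SOLUTE_CHARGE_SCALE, n_atoms)
    charges -= charges.mean()

    bonds = [BondedTerm("bond", (i, i + 1), _SOLUTE_BOND_K, _SOLUTE_BOND_R0)
             for i in range(n_atoms - 1)]
    angles = [BondedTerm("angle", (i, i + 1, i + 2), _SOLUTE_ANGLE_K, _SOLUTE_ANGLE_T0)
              for i in range(n_atoms - 2)]
    dihedrals = [BondedTerm("dihedral", (i, i + 1, i + 2, i + 3), _SOLUTE_DIHEDRAL_K,
                            periodicity=3) for i in range(n_atoms - 3)]
    excluded, scaled = auto_exclusions(n_atoms, bonds)

    s6 = _SOLUTE_SIGMA**6
    lj_A = np.full(n_atoms, 4.0 * _SOLUTE_EPSILON * s6 * s6)
    lj_B = np.full(n_atoms, 4.0 * _SOLUTE_EPSILON * s6)
    params = SurrogateMLParams(
        elements=["C"] * n_atoms,
        charges=charges, lj_A=lj_A, lj_B=lj_B,
        bonded_terms=bonds + angles + dihedrals,
        exclusions=excluded, pairs14=scaled,
    )

    atoms = [Atom(i, "C", 12.011, charges[i], lj_A[i], lj_B[i], "ML")
             for i in range(n_atoms)]
    system = System(atoms=atoms, ml_potential=params.build(), rigid_ml=not flexible)

    # Zigzag chain geometry at the equilibrium bond length and angle.
    coords = np.zeros((n_atoms, 3))
    step = _SOLUTE_BOND_R0 * math.sin(_SOLUTE_ANGLE_T0 / 2.0)
    rise = _SOLUTE_BOND_R0 * math.cos(_SOLUTE_ANGLE_T0 / 2.0)
    for i in range(n_atoms):
        coords[i] = (i * step, (i % 2) * rise, 0.0)
    return system, params, Frame(coords)


# ---------------------------------------------------------------------------
# Solvent bath
# ---------------------------------------------------------------------------

def _triatomic_template(model: dict) -> np.ndarray:
    r0, t0 = model["bond_r0"], model["angle_theta0"]
    return np.array([
        [0.0, 0.0, 0.0],
        [r0 * math.sin(t0 / 2.0), r0 * math.cos(t0 / 2.0), 0.0],
        [-r0 * math.sin(t0 / 2.0), r0 * math.cos(t0 / 2.0), 0.0],
    ])


def make_solvent_bath(n_molecules: int, box_edge: float = 12.0,
                      model: str = "lj_charge_triatomic", seed: int = 0,
                      periodic: bool = False, cavity_radius: float = 0.0,
                      min_distance: float = 1.5, max_attempts: int = 20000
                      ) -> tuple[System, Frame]:
    """An MM-region solvent bath placed by rejection sampling.

    Molecules are dropped at random positions/orientations inside a cube of
    edge ``box_edge`` centred on the origin, rejecting placements that bring
    any two atoms of different molecules closer than ``min_distance`` (A) or
    enter the optional spherical cavity around the origin (where a solute
    will sit).  ``periodic=True`` stores the cube as an orthorhombic box and
    enables minimum-image interactions; the default is an open droplet.
    """
    if model not in ("lj_charge_triatomic", "lj_monatomic"):
        raise ValueError(f"unknown solvent model {model!r}")
    rng = np.random.default_rng(seed)
    per_mol = 3 if model == "lj_charge_triatomic" else 1
    template = _triatomic_template(TRIATOMIC_SOLVENT) if per_mol == 3 else np.zeros((1, 3))
    template = template - template.mean(axis=0)

    placed: list[np.ndarray] = []
    attempts = 0
    half = box_edge / 2.0
    while len(placed) < n_molecules:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not pack {n_molecules} molecules into a {box_edge} A cube "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        com = rng.uniform(-half, half, 3)
        if cavity_radius > 0 and np.linalg.norm(com) < cavity_radius:
            continue
        rot = Rotation.random(random_state=rng).as_matrix()
        mol = com + template @ rot.T
        ok = True
        for other in placed:
            d = np.linalg.norm(mol[:, None, :] - other[None, :, :], axis=-1)
            if d.min() < min_distance:
                ok = False
                break
        if ok:
            placed.append(mol)

    atoms: list[Atom] = []
    bonds: list[BondedTerm] = []
    angles: list[BondedTerm] = []
    coords = np.concatenate(placed)
    for m in range(n_molecules):
        base = m * per_mol
        if per_mol == 3:
            w = TRIATOMIC_SOLVENT
            from .system_model import ELEMENT_MASSES, lj_ab_from_sigma_epsilon

            for k in range(3):
                A, B = lj_ab_from_sigma_epsilon(w["sigma"][k], w["epsilon"][k])
                atoms.append(Atom(base + k, w["elements"][k],
                                  ELEMENT_MASSES[w["elements"][k]],
                                  w["charges"][k], A, B, "MM"))
            bonds.append(BondedTerm("bond", (base, base + 1), w["bond_k"], w["bond_r0"]))
            bonds.append(BondedTerm("bond", (base, base + 2), w["bond_k"], w["bond_r0"]))
            angles.append(BondedTerm("angle", (base + 1, base, base + 2),
                                     w["angle_k"], w["angle_theta0"]))
        else:
            from .system_model import ELEMENT_MASSES, lj_ab_from_sigma_epsilon

            a = MONATOMIC_SOLVENT
            A, B = lj_ab_from_sigma_epsilon(a["sigma"], a["epsilon"])
            atoms.append(Atom(base, a["element"], ELEMENT_MASSES[a["element"]],
                              a["charge"], A, B, "MM"))

    excluded, scaled = auto_exclusions(len(atoms), bonds)
    system = System(atoms=atoms, bonded_terms=bonds + angles,
                    exclusions=excluded, pairs14=scaled,
                    box=np.full(3, box_edge) if periodic else None)
    return system, Frame(coords)


def combine_solute_bath(solute: System, solute_frame: Frame,
                        bath: System, bath_frame: Frame) -> tuple[System, Frame]:
    """Merge an ML-region solute (placed at the origin) with an MM bath.

    Solute atoms come first and keep their ML tags; bath atoms, bonded terms
    and exclusions are re-indexed after them.  Generate the bath with a
    ``cavity_radius`` large enough to hold the solute to avoid clashes.
    """
    n_s = solute.n_atoms
    solute_coords = solute_frame.coordinates - solute_frame.coordinates.mean(axis=0)
    atoms = [Atom(a.index, a.element, a.mass, a.charge, a.lj_A, a.lj_B, "ML")
             for a in solute.atoms]
    atoms += [Atom(n_s + a.index, a.element, a.mass, a.charge, a.lj_A, a.lj_B, "MM")
              for a in bath.atoms]
    shift = lambda t: BondedTerm(t.kind, tuple(n_s + i for i in t.atoms),
                                 t.force_constant, t.equilibrium, t.periodicity, t.phase)
    system = System(
        atoms=atoms,
        bonded_terms=[shift(t) for t in bath.bonded_terms],
        exclusions={(i + n_s, j + n_s) for i, j in bath.exclusions},
        pairs14={(i + n_s, j + n_s) for i, j in bath.pairs14},
        box=bath.box,
        ml_potential=solute.ml_potential,
        rigid_ml=solute.rigid_ml,
    )
    coords = np.concatenate([solute_coords, bath_frame.coordinates])
    return system, Frame(coords)


# ---------------------------------------------------------------------------
# Harmonic ensembles and 1D oracle systems
# ---------------------------------------------------------------------------

def make_harmonic_ensemble(n_atoms: int, per_coordinate_variance: float,
                           n_frames: int, seed: int = 0,
                           mean_coords: np.ndarray | None = None) -> Trajectory:
    """Independent isotropic Gaussian wobble about fixed mean positions.

    Ground truth for B-factor recovery: every coordinate fluctuates with the
    given variance (A^2), so B = 8 pi^2 * variance for every atom.  Frames
    share a common reference (no net rigid-body motion is added), so they can
    be analysed without superposition.
    """
    if per_coordinate_variance < 0:
        raise ValueError("variance must be non-negative")
    rng = np.random.default_rng(seed)
    if mean_coords is None:
        mean_coords = rng.uniform(-10.0, 10.0, (n_atoms, 3))
    sd = math.sqrt(per_coordinate_variance)
    frames = [
        Frame(mean_coords + sd * rng.standard_normal((n_atoms, 3)), time=float(t))
        for t in range(n_frames)
    ]
    return Trajectory(frames)


@dataclass
class Harmonic1D:
    """V(x) = 1/2 k (x - x0)^2 with analytic energy, force and free energy."""

    k: float
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("stiffness must be positive")

    def energy(self, x: float) -> float:
        return 0.5 * self.k * (x - self.x0) ** 2

    __call__ = energy

    def force(self, x: float) -> float:
        return -self.k * (x - self.x0)


def make_harmonic_1d(k0: float, k1: float, temperature: float
                     ) -> tuple[Harmonic1D, Harmonic1D, float]:
    """Paired 1D harmonic endpoint states and their exact dG.

    For Z proportional to 1/sqrt(k), dG = (kT/2) ln(k1/k0); swapping the
    endpoints negates it.
    """
    p0, p1 = Harmonic1D(k0), Harmonic1D(k1)
    dg = 0.5 * thermal_energy(temperature) * math.log(k1 / k0)
    return p0, p1, dg


def make_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    if spec.kind == "toy_solute":
        return make_toy_solute(spec.n_atoms, spec.flexible, spec.seed)
    if spec.kind == "solvent_bath":
        return make_solvent_bath(spec.n_molecules, spec.box_edge, spec.model, spec.seed)
    if spec.kind == "harmonic_ensemble":
        return make_harmonic_ensemble(spec.n_atoms, spec.variance, spec.n_frames, spec.seed)
    if spec.kind == "harmonic_1d":
        return make_harmonic_1d(spec.k0, spec.k1, spec.temperature)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
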