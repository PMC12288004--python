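"""Domain types and file I/O for hybrid ML/MM systems.

A :class:`System` partitions its atoms into an *ML region* — described by an
opaque machine-learning potential through :class:`MLPotentialContract` — and
an *MM region* described by a classical force field (bonded terms plus
Lennard-Jones and Coulomb nonbonded interactions).  The two regions interact
only through nonbonded coupling (mechanical embedding); no covalent bond may
cross the region boundary.

Topology file format
--------------------
Topologies are plain YAML of this package's own design::

    atoms:                       # one entry per atom, file order = atom index
      - {element: O, mass: 15.999, charge: -0.834, sigma: 3.15, epsilon: 0.152}
      - {element: H, charge: 0.417}            # mass defaults from the element
    bonds:                       # harmonic: E = 1/2 k (r - r0)^2
      - {i: 0, j: 1, k: 450.0, r0: 0.9572}
    angles:                      # harmonic: E = 1/2 k (theta - theta0)^2, rad
      - {i: 0, j: 1, l: 2, k: 55.0, theta0: 1.8242}
    dihedrals:                   # cosine: E = k (1 + cos(n phi - phase))
      - {i: 0, j: 1, l: 2, m: 3, k: 0.2, n: 3, phase: 0.0}
    exclusions: auto             # 1-2/1-3 excluded, 1-4 scaled (default), or
                                 # an explicit list of [i, j] pairs
    ml_selection: "0-5"          # ML-region atoms: range string or index list
    ml_potential:                # surrogate ML parameters over the ML atoms
      bonds: [...]               # same record shapes as above, global indices
      angles: [...]
      dihedrals: [...]
    box: [18.0, 18.0, 18.0]      # optional orthorhombic box edges, A

Per-atom Lennard-Jones parameters may be given either as ``sigma``/``epsilon``
(A, kcal/mol; Lorentz-Berthelot combining applied at evaluation time) or as
the self-pair coefficients ``lj_A`` (kcal*A^12/mol) and ``lj_B``
(kcal*A^6/mol).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Atom",
    "BondedTerm",
    "Frame",
    "MLPotentialContract",
    "ParseError",
    "System",
    "Trajectory",
    "load_system",
    "load_topology",
    "read_pdb",
    "read_xyz",
    "read_trajectory_xyz",
    "write_energy_table",
    "write_trajectory",
]

# Average atomic masses (amu) for the elements the toy systems use.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ar": 39.948, "Br": 79.904, "I": 126.904,
}


class ParseError(ValueError):
    """Raised for malformed coordinate or topology files."""


@dataclass
class Atom:
    """One particle: identity, charge, LJ self-parameters and region tag.

    ``lj_A``/``lj_B`` are the self-pair 12-6 coefficients A_ii = 4 eps sigma^12
    and B_ii = 4 eps sigma^6; heteropairs are combined with Lorentz-Berthelot
    rules on the recovered (sigma, eps).
    """

    index: int
    element: str
    mass: float
    charge: float
    lj_A: float = 0.0
    lj_B: float = 0.0
    region: str = "MM"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.index}: mass must be positive, got {self.mass}")
        if self.lj_A < 0 or self.lj_B < 0:
            raise ValueError(f"atom {self.index}: LJ coefficients must be non-negative")
        if self.region not in ("ML", "MM"):
            raise ValueError(f"atom {self.index}: region must be 'ML' or 'MM', got {self.region!r}")

    @property
    def sigma_epsilon(self) -> tuple[float, float]:
        """Recover (sigma, epsilon) from the A/B self-coefficients."""
        if self.lj_A <= 0 or self.lj_B <= 0:
            return 0.0, 0.0
        sigma6 = self.lj_A / self.lj_B
        return sigma6 ** (1.0 / 6.0), self.lj_B**2 / (4.0 * self.lj_A)


def lj_ab_from_sigma_epsilon(sigma: float, epsilon: float) -> tuple[float, float]:
    """Self-pair 12-6 coefficients (A, B) from sigma (A) and epsilon (kcal/mol)."""
    s6 = sigma**6
    return 4.0 * epsilon * s6 * s6, 4.0 * epsilon * s6


@dataclass
class BondedTerm:
    """A harmonic bond/angle or a cosine dihedral.

    * bond:     atoms=(i, j),       E = 1/2 k (r - equilibrium)^2
    * angle:    atoms=(i, j, l),    E = 1/2 k (theta - equilibrium)^2
    * dihedral: atoms=(i, j, l, m), E = k (1 + cos(periodicity*phi - phase))
    """

    kind: str
    atoms: tuple[int, ...]
    force_constant: float
    equilibrium: float = 0.0
    periodicity: int = 0
    phase: float = 0.0

    _ARITY = {"bond": 2, "angle": 3, "dihedral": 4}

    def __post_init__(self) -> None:
        if self.kind not in self._ARITY:
            raise ValueError(f"unknown bonded term kind {self.kind!r}")
        self.atoms = tuple(int(a) for a in self.atoms)
        if len(self.atoms) != self._ARITY[self.kind]:
            raise ValueError(f"{self.kind} term needs {self._ARITY[self.kind]} atoms, got {self.atoms}")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"{self.kind} term has repeated atom indices {self.atoms}")
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if self.kind == "dihedral" and self.periodicity < 1:
            raise ValueError("dihedral periodicity must be >= 1")


@runtime_checkable
class MLPotentialContract(Protocol):
    """The pluggable, deliberately indivisible ML-potential interface.

    An implementation returns exactly one total energy (kcal/mol) and the
    per-atom forces (kcal/mol/A) for the ML-region atoms.  No bonded/nonbonded
    or any other component breakdown is exposed: downstream code (notably the
    alchemical machinery) must work with the single scalar, which is the
    premise the free-energy scheme is built on.  Forces must equal the
    negative coordinate gradient of the returned energy.

    Adapters for external calculators (e.g. an ASE calculator or a TorchANI
    model) only need an ``evaluate`` method with this signature.
    """

    def evaluate(
        self, elements: Sequence[str], coordinates: np.ndarray
    ) -> tuple[float, np.ndarray]: ...


@dataclass
class Frame:
    """Coordinates (A) and velocities (A/fs) for every atom at one time (fs)."""

    coordinates: np.ndarray
    velocities: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(f"coordinates must have shape (N, 3), got {self.coordinates.shape}")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.coordinates)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise ValueError("velocities must match coordinates in shape")
        if not np.all(np.isfinite(self.coordinates)) or not np.all(np.isfinite(self.velocities)):
            raise ValueError("non-finite coordinate or velocity encountered")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.velocities.copy(), self.time)


class Trajectory:
    """An ordered sequence of frames with optional per-frame energy reports."""

    def __init__(self, frames: Iterable[Frame] = (), energies: list | None = None):
        self.frames: list[Frame] = list(frames)
        self.energies = energies if energies is not None else []
        self._check_monotonic()

    def _check_monotonic(self) -> None:
        times = [f.time for f in self.frames]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be monotonically increasing")

    def append(self, frame: Frame, energy=None) -> None:
        if self.frames and frame.time < self.frames[-1].time:
            raise ValueError("frame times must be monotonically increasing")
        self.frames.append(frame)
        if energy is not None:
            self.energies.append(energy)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, idx) -> Frame:
        return self.frames[idx]

    def coordinate_array(self) -> np.ndarray:
        """Stack all coordinates into an (n_frames, N, 3) array."""
        return np.stack([f.coordinates for f in self.frames])


def _normalize_pair(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise ValueError(f"pair ({i}, {j}) repeats an atom")
    return (i, j) if i < j else (j, i)


@dataclass
class System:
    """Atoms, MM bonded terms, exclusions, region partition and ML potential.

    ``exclusions`` are fully excluded nonbonded pairs (1-2 and 1-3);
    ``pairs14`` are pairs whose nonbonded interaction is scaled by the 1-4
    factors.  Both apply within the MM region (and, separately, inside a
    surrogate ML potential); no exclusions apply across the ML/MM boundary
    because no covalent bond crosses it.

    ``rigid_ml`` freezes the internal geometry of the ML region during
    dynamics: the region moves as one translating body, so its internal
    coordinates — and hence the ML energy of an isolated conformer — are
    preserved exactly.
    """

    atoms: list[Atom]
    bonded_terms: list[BondedTerm] = field(default_factory=list)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    pairs14: set[tuple[int, int]] = field(default_factory=set)
    box: np.ndarray | None = None
    ml_potential: MLPotentialContract | None = None
    scale14_coulomb: float = 1.0 / 1.2
    scale14_lj: float = 0.5
    rigid_ml: bool = False

    def __post_init__(self) -> None:
        for pos, atom in enumerate(self.atoms):
            if atom.index != pos:
                raise ValueError(f"atom at position {pos} carries index {atom.index}")
        n = len(self.atoms)
        ml = set(self.ml_indices)
        for term in self.bonded_terms:
            for a in term.atoms:
                if not 0 <= a < n:
                    raise ValueError(f"bonded term {term.kind}{term.atoms} references atom {a} out of range")
            in_ml = [a in ml for a in term.atoms]
            if any(in_ml):
                raise ValueError(
                    f"bonded term {term.kind}{term.atoms} touches the ML region; "
                    "MM bonded terms may not span or enter it (no covalent cuts)"
                )
        self.exclusions = {_normalize_pair(i, j) for i, j in self.exclusions}
        self.pairs14 = {_normalize_pair(i, j) for i, j in self.pairs14} - self.exclusions
        for i, j in self.exclusions | self.pairs14:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"exclusion pair ({i}, {j}) out of range")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive orthorhombic edge lengths")
        if ml and self.ml_potential is None:
            raise ValueError("system has ML atoms but no ML potential bound")
        self._cache: dict = {}

    # -- region bookkeeping -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ml_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.region == "ML"], dtype=int)

    @property
    def mm_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.region == "MM"], dtype=int)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def ml_elements(self) -> list[str]:
        return [self.atoms[i].element for i in self.ml_indices]


def parse_selection(sel, n_atoms: int) -> list[int]:
    """Parse an ML-selection: an index list or a '0-5'/'0-5,8' range string."""
    if sel is None:
        return []
    if isinstance(sel, str):
        indices: list[int] = []
        for chunk in sel.split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "-" in chunk:
                lo, hi = chunk.split("-", 1)
                indices.extend(range(int(lo), int(hi) + 1))
            else:
                indices.append(int(chunk))
    else:
        indices = [int(i) for i in sel]
    for i in indices:
        if not 0 <= i < n_atoms:
            raise ParseError(f"ml_selection index {i} out of range for {n_atoms} atoms")
    if len(set(indices)) != len(indices):
        raise ParseError("ml_selection assigns a region to some atom more than once")
    return sorted(indices)


# ---------------------------------------------------------------------------
# Coordinate files
# ---------------------------------------------------------------------------

def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read the first block of an XYZ file -> (elements, (N, 3) coordinates)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}, line 1: expected an atom count, got {lines[0]!r}") from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}: header declares {n} atoms but only {len(lines) - 2} records follow")
    elements, coords = [], []
    for ln in range(2, 2 + n):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {ln + 1}: malformed XYZ record {lines[ln]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}, line {ln + 1}: non-numeric coordinate in {lines[ln]!r}") from None
        elements.append(parts[0])
        coords.append(xyz)
    return elements, np.array(coords)


def read_trajectory_xyz(path) -> tuple[list[str], Trajectory]:
    """Read a multi-block XYZ trajectory; times are taken as the block index (fs)."""
    lines = Path(path).read_text().splitlines()
    frames, elements = [], None
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].split()[0])
        except ValueError:
            raise ParseError(f"{path}, line {ln + 1}: expected an atom count, got {lines[ln]!r}") from None
        block = lines[ln + 2 : ln + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}, line {ln + 1}: truncated block ({len(block)}/{n} records)")
        els = [rec.split()[0] for rec in block]
        coords = np.array([[float(v) for v in rec.split()[1:4]] for rec in block])
        if elements is None:
            elements = els
        elif els != elements:
            raise ParseError(f"{path}, line {ln + 1}: element order changes between blocks")
        frames.append(Frame(coords, time=float(len(frames))))
        ln += 2 + n
    if not frames:
        raise ParseError(f"{path}: no XYZ blocks found")
    return elements, Trajectory(frames)


def read_pdb(path) -> tuple[list[str], np.ndarray]:
    """Read a PDB file (first model) -> (elements, coordinates) via MDAnalysis."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(str(path))
        except Exception as exc:  # MDAnalysis raises a zoo of types
            raise ParseError(f"{path}: could not parse PDB file ({exc})") from exc
        atoms = universe.atoms
        try:
            elements = [el.capitalize() for el in atoms.elements]
        except Exception:
            # Fall back to the leading letters of the atom name.
            elements = ["".join(c for c in name if c.isalpha())[:2].capitalize() or "X"
                        for name in atoms.names]
        coords = atoms.positions.astype(float).copy()
    return elements, coords


def read_coordinates(path) -> tuple[list[str], np.ndarray]:
    """Dispatch on file extension (.xyz or .pdb)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path)
    if suffix == ".pdb":
        return read_pdb(path)
    raise ParseError(f"{path}: unsupported coordinate format {suffix!r} (use .xyz or .pdb)")


def _write_xyz(traj: Trajectory, elements: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for frame in traj:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"t = {frame.time:.4f} fs\n")
            for el, (x, y, z) in zip(elements, frame.coordinates):
                fh.write(f"{el:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def _write_pdb(traj: Trajectory, elements: Sequence[str], path) -> None:
    import MDAnalysis as mda

    n = traj[0].n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(n, trajectory=True)
        universe.add_TopologyAttr("names", [f"{el}{i + 1}" for i, el in enumerate(elements)])
        universe.add_TopologyAttr("elements", [el.upper() for el in elements])
        universe.add_TopologyAttr("resnames", ["MOL"])
        universe.add_TopologyAttr("resids", [1])
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as writer:
            for frame in traj:
                universe.atoms.positions = frame.coordinates
                writer.write(universe.atoms)


def write_trajectory(traj: Trajectory, path, fmt: str | None = None,
                     elements: Sequence[str] | None = None) -> None:
    """Write a trajectory as multi-block XYZ or multi-model PDB.

    ``fmt`` defaults from the file extension.  ``elements`` must be supplied
    (one symbol per atom); a bare coordinate dump has no other source for them.
    """
    if len(traj) == 0:
        raise ValueError("cannot write an empty trajectory")
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if elements is None:
        raise ValueError("write_trajectory requires the element list")
    if len(elements) != traj[0].n_atoms:
        raise ValueError("element list length does not match atom count")
    fmt = fmt.upper()
    if fmt == "XYZ":
        _write_xyz(traj, elements, path)
    elif fmt == "PDB":
        _write_pdb(traj, elements, path)
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r} (use XYZ or PDB)")


def write_energy_table(reports, path) -> pd.DataFrame:
    """Serialize per-frame energy reports to CSV (kcal/mol columns, time in fs)."""
    rows = [
        {
            "time_fs": r.time,
            "E_ML": r.E_ML,
            "E_MM": r.E_MM,
            "E_coupling": r.E_coupling,
            "E_kinetic": r.E_kinetic,
            "E_total": r.E_total,
        }
        for r in reports
    ]
    table = pd.DataFrame(rows, columns=["time_fs", "E_ML", "E_MM", "E_coupling", "E_kinetic", "E_total"])
    table.to_csv(path, index=False)
    return table


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _atom_from_record(idx: int, rec: dict, region: str) -> Atom:
    if "element" not in rec:
        raise ParseError(f"topology atom {idx}: missing 'element'")
    element = str(rec["element"])
    mass = rec.get("mass")
    if mass is None:
        mass = ELEMENT_MASSES.get(element)
        if mass is None:
            raise ParseError(f"topology atom {idx}: unknown element {element!r} and no mass given")
    if "sigma" in rec or "epsilon" in rec:
        lj_A, lj_B = lj_ab_from_sigma_epsilon(float(rec.get("sigma", 0.0)), float(rec.get("epsilon", 0.0)))
    else:
        lj_A, lj_B = float(rec.get("lj_A", 0.0)), float(rec.get("lj_B", 0.0))
    return Atom(index=idx, element=element, mass=float(mass),
                charge=float(rec.get("charge", 0.0)), lj_A=lj_A, lj_B=lj_B, region=region)


def _bonded_from_records(section: list | None, kind: str) -> list[BondedTerm]:
    terms = []
    for rec in section or []:
        keys = {"bond": ("i", "j"), "angle": ("i", "j", "l"), "dihedral": ("i", "j", "l", "m")}[kind]
        try:
            atoms = tuple(int(rec[k]) for k in keys)
        except KeyError as exc:
            raise ParseError(f"topology {kind} record {rec!r}: missing index {exc}") from None
        if kind == "dihedral":
            terms.append(BondedTerm(kind, atoms, float(rec["k"]),
                                    periodicity=int(rec.get("n", 1)),
                                    phase=float(rec.get("phase", 0.0))))
        else:
            eq_key = "r0" if kind == "bond" else "theta0"
            terms.append(BondedTerm(kind, atoms, float(rec["k"]), equilibrium=float(rec[eq_key])))
    return terms


def auto_exclusions(n_atoms: int, bonds: Iterable[BondedTerm],
                    dihedrals: Iterable[BondedTerm] = ()) -> tuple[set, set]:
    """Derive (excluded, scaled-1-4) pair sets from bond connectivity.

    1-2 and 1-3 pairs are fully excluded; 1-4 pairs (three bonds apart) are
    returned separately for scaled interactions.
    """
    neighbors: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for b in bonds:
        if b.kind != "bond":
            continue
        i, j = b.atoms
        neighbors[i].add(j)
        neighbors[j].add(i)
    excluded: set[tuple[int, int]] = set()
    scaled: set[tuple[int, int]] = set()
    for i in range(n_atoms):
        one_two = neighbors[i]
        one_three = set().union(*(neighbors[j] for j in one_two)) - {i} if one_two else set()
        one_four = (set().union(*(neighbors[j] for j in one_three)) - {i} - one_two
                    if one_three else set())
        for j in one_two | (one_three - one_two):
            excluded.add(_normalize_pair(i, j))
        for j in one_four - one_two - one_three:
            scaled.add(_normalize_pair(i, j))
    return excluded, scaled - excluded


def load_topology(path) -> dict:
    """Parse the YAML topology file into a raw, validated dictionary."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f", line {mark.line + 1}" if mark is not None else ""
        raise ParseError(f"{path}{line}: invalid YAML ({exc})") from exc
    if not isinstance(doc, dict) or "atoms" not in doc:
        raise ParseError(f"{path}: topology must be a mapping with an 'atoms' section")
    return doc


def build_system(topology: dict, *, rigid_ml: bool = False) -> System:
    """Construct a :class:`System` (with a bound surrogate ML potential) from
    a parsed topology dictionary."""
    records = topology["atoms"]
    n = len(records)
    ml_set = set(parse_selection(topology.get("ml_selection"), n))
    atoms = [_atom_from_record(i, rec, "ML" if i in ml_set else "MM")
             for i, rec in enumerate(records)]

    bonds = _bonded_from_records(topology.get("bonds"), "bond")
    angles = _bonded_from_records(topology.get("angles"), "angle")
    dihedrals = _bonded_from_records(topology.get("dihedrals"), "dihedral")
    all_terms = bonds + angles + dihedrals

    excl_spec = topology.get("exclusions", "auto")
    if excl_spec == "auto" or excl_spec is None:
        excluded, scaled = auto_exclusions(n, bonds, dihedrals)
    else:
        excluded = {_normalize_pair(int(i), int(j)) for i, j in excl_spec}
        scaled = set()

    ml_potential = None
    if ml_set:
        from .potentials import SurrogateMLParams  # deferred: avoids module cycle

        ml_sorted = sorted(ml_set)
        params = SurrogateMLParams.from_topology(
            topology.get("ml_potential", {}), atoms, ml_sorted
        )
        ml_potential = params.build()

    # System-level terms / exclusions are the MM-region subset.
    def _all_mm(idx: Iterable[int]) -> bool:
        return all(a not in ml_set for a in idx)

    return System(
        atoms=atoms,
        bonded_terms=[t for t in all_terms if _all_mm(t.atoms)],
        exclusions={p for p in excluded if _all_mm(p)},
        pairs14={p for p in scaled if _all_mm(p)},
        box=topology.get("box"),
        ml_potential=ml_potential,
        rigid_ml=rigid_ml,
    )


def load_system(coord_path, topology_path) -> tuple[System, Frame]:
    """Load coordinates plus topology into a (System, Frame) pair.

    The two files must agree on atom count and element ordering; mismatches
    raise :class:`ParseError` naming both sides.
    """
    elements, coords = read_coordinates(coord_path)
    topology = load_topology(topology_path)
    system = build_system(topology)
    if system.n_atoms != len(elements):
        raise ParseError(
            f"atom count mismatch: {coord_path} has {len(elements)} atoms, "
            f"{topology_path} declares {system.n_atoms}"
        )
    for i, (file_el, top_el) in enumerate(zip(elements, system.elements)):
        if file_el.capitalize() != top_el.capitalize():
            raise ParseError(
                f"element mismatch at atom {i}: coordinate file says {file_el!r}, "
                f"topology says {top_el!r}"
            )
    return system, Frame(coords)
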