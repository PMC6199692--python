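"""Core data model: molecular systems, snapshots and internal coordinates.

A :class:`MolecularSystem` holds atoms, masses, charges and the bonded /
nonbonded force-field terms of a (toy) solute-plus-environment system.  A
:class:`Snapshot` is the unit every sampling protocol transforms: synchronized
positions and velocities with a time stamp and a provenance ("stage") tag.
Internal coordinates (distances, angles, dihedrals) are evaluated on
snapshots and are invariant under rigid-body motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import AMU_A2_FS2_TO_EV

__all__ = [
    "BondTerm",
    "AngleTerm",
    "TorsionTerm",
    "MolecularSystem",
    "Snapshot",
    "InternalCoordinate",
    "DegenerateGeometryError",
    "evaluate_internal",
    "kinetic_energy_per_atom",
]

#: default masses (amu) for the element symbols the toy systems use
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Cl": 35.45,
    "M": 100.0,  # generic heavy central atom of the toy chromophore
    "W": 18.015,  # single-site solvent particle
}


class DegenerateGeometryError(ValueError):
    """Raised when a geometric coordinate is undefined (collinear atoms)."""


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond V = k (r - r0)^2, k in eV/A^2, r0 in A."""

    i: int
    j: int
    k: float
    r0: float


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle V = k (theta - theta0)^2, k in eV/rad^2, theta0 in deg."""

    i: int
    j: int
    k: int
    kf: float
    theta0: float


@dataclass(frozen=True)
class TorsionTerm:
    """Cosine torsion V = sum_m (barrier_m/2) (1 + cos(n_m phi - gamma_m)).

    ``terms`` is a tuple of (barrier eV, periodicity, phase deg).
    """

    i: int
    j: int
    k: int
    l: int
    terms: tuple[tuple[float, int, float], ...]


@dataclass
class MolecularSystem:
    """Atoms, masses, charges and force-field terms of a simulation substrate.

    ``groups`` assigns each atom the label ``"solute"`` or ``"environment"``;
    the two labels partition the atom set.  ``frozen`` lists atoms that are
    permanently immobile (excluded from integration and DOF counts).
    """

    symbols: list[str]
    masses: np.ndarray
    charges: np.ndarray
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionTerm] = field(default_factory=list)
    lj_epsilon: np.ndarray | None = None  # eV, per atom
    lj_sigma: np.ndarray | None = None  # A, per atom
    frozen: frozenset[int] = frozenset()
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.symbols)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.lj_epsilon is None:
            self.lj_epsilon = np.zeros(n)
        if self.lj_sigma is None:
            self.lj_sigma = np.full(n, 3.0)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        if not self.groups:
            self.groups = ["solute"] * n
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def validate(self) -> None:
        n = self.n_atoms
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive and one per atom")
        if self.charges.shape != (n,):
            raise ValueError("charges must be one per atom")
        if len(self.groups) != n:
            raise ValueError("groups must label every atom")
        if set(self.groups) - {"solute", "environment"}:
            raise ValueError("group labels must be 'solute' or 'environment'")
        for term in self.bonds:
            idx: tuple[int, ...] = (term.i, term.j)
            self._check_indices(idx, n)
        for term in self.angles:
            self._check_indices((term.i, term.j, term.k), n)
        for term in self.torsions:
            self._check_indices((term.i, term.j, term.k, term.l), n)
        if any(i < 0 or i >= n for i in self.frozen):
            raise ValueError("frozen set references invalid atom index")

    @staticmethod
    def _check_indices(idx: tuple[int, ...], n: int) -> None:
        if len(set(idx)) != len(idx):
            raise ValueError(f"bonded term repeats atom indices: {idx}")
        if any(i < 0 or i >= n for i in idx):
            raise ValueError(f"bonded term references invalid atom index: {idx}")

    def group_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == label], dtype=int)

    @property
    def solute(self) -> np.ndarray:
        return self.group_indices("solute")

    @property
    def environment(self) -> np.ndarray:
        return self.group_indices("environment")

    def mobile_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_atoms) if i not in self.frozen], dtype=int)

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            symbols=list(self.symbols),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            bonds=list(self.bonds),
            angles=list(self.angles),
            torsions=list(self.torsions),
            lj_epsilon=self.lj_epsilon.copy(),
            lj_sigma=self.lj_sigma.copy(),
            frozen=frozenset(self.frozen),
            groups=list(self.groups),
        )


STAGES = ("production", "heated", "reequilibrated", "refined", "wigner", "initial")


@dataclass
class Snapshot:
    """Synchronized positions (A) and velocities (A/fs) with provenance."""

    positions: np.ndarray
    velocities: np.ndarray
    time_fs: float = 0.0
    stage: str = "initial"
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise ValueError("positions and velocities must both be (n_atoms, 3)")
        if self.positions.shape[1] != 3:
            raise ValueError("coordinates must be 3-dimensional")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage tag {self.stage!r}; use one of {STAGES}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self, **updates) -> "Snapshot":
        snap = Snapshot(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            time_fs=self.time_fs,
            stage=self.stage,
            seed=self.seed,
            meta=dict(self.meta),
        )
        for key, value in updates.items():
            setattr(snap, key, value)
        return snap


@dataclass(frozen=True)
class InternalCoordinate:
    """A named distance, angle or dihedral over atom indices.

    Conventions: distances >= 0 (A); angles in [0, 180] deg; dihedrals follow
    the IUPAC right-handed sign convention with range (-180, +180] deg.
    """

    kind: str
    indices: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        expected = {"distance": 2, "angle": 3, "dihedral": 4}
        if self.kind not in expected:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        if len(self.indices) != expected[self.kind]:
            raise ValueError(f"{self.kind} needs {expected[self.kind]} atom indices")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("coordinate repeats atom indices")

    def evaluate(self, positions: np.ndarray) -> float:
        positions = np.asarray(positions, dtype=float)
        r = positions[list(self.indices)]
        if self.kind == "distance":
            return float(np.linalg.norm(r[1] - r[0]))
        if self.kind == "angle":
            return _angle_deg(r[0], r[1], r[2])
        return _dihedral_deg(r[0], r[1], r[2], r[3])


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("coincident atoms in angle")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError(
            "three consecutive atoms are collinear; dihedral undefined"
        )
    b2n = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2n)
    phi = float(np.degrees(np.arctan2(y, x)))
    if phi <= -180.0:
        phi += 360.0
    return phi


def evaluate_internal(coord: InternalCoordinate, snapshot: Snapshot | np.ndarray) -> float:
    """Evaluate an internal coordinate on a snapshot (or raw positions)."""
    positions = snapshot.positions if isinstance(snapshot, Snapshot) else snapshot
    n = np.asarray(positions).shape[0]
    if any(i < 0 or i >= n for i in coord.indices):
        raise IndexError(f"coordinate {coord.name or coord.kind} indices out of range")
    return coord.evaluate(np.asarray(positions))


def kinetic_energy_per_atom(snapshot: Snapshot, masses: Sequence[float]) -> np.ndarray:
    """Per-atom kinetic energies E_i = 0.5 m_i |v_i|^2 in eV."""
    masses = np.asarray(masses, dtype=float)
    if snapshot.velocities is None or not np.all(np.isfinite(snapshot.velocities)):
        raise ValueError("snapshot has no finite velocities")
    if masses.shape[0] != snapshot.n_atoms:
        raise ValueError("mass array does not match atom count")
    v2 = np.einsum("ij,ij->i", snapshot.velocities, snapshot.velocities)
    return 0.5 * masses * v2 * AMU_A2_FS2_TO_EV


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(angle) or np.asarray(angle).ndim == 0:
        return float(wrapped)
    return wrapped
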