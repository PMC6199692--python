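"""Self-contained toy systems for exercising every sampling protocol.

The central fixture is an 8-atom *toy chromophore*: a heavy central atom M, a
rigid planar 4-atom ring ligand on one side, and a 3-atom rotor ligand
(anchor N plus two marker atoms H1/H2 whose distance defines the rotor
"width") on the other.  A cosine torsion potential on the ring-M-N-H1
dihedral gives the rotor three minima per period near theta = -90, 0, +90
deg with the central conformer deepest; energy differences and barriers are
of the order of 1 kcal/mol, so at 300 K the rotor is almost free.  The
lowest normal mode of the isolated chromophore is this torsion.

A droplet of single-site Lennard-Jones solvent particles (optionally) wraps
the chromophore; a *refined* variant of the force field (shifted equilibrium
bond/angle values, same topology) stands in for a higher-level potential in
refinement studies; a linear-plus-noise excitation model maps geometries to
vertical excitation tables so spectral shifts are analytically predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcefield import PotentialModel, Wall
from .md import maxwell_boltzmann_velocities
from .normalmodes import NormalModeSet
from .spectra import ExcitationTable
from .system import (
    AngleTerm,
    BondTerm,
    InternalCoordinate,
    MolecularSystem,
    Snapshot,
    TorsionTerm,
    evaluate_internal,
)
from .units import KB

__all__ = [
    "ToyChromophoreSpec",
    "ToyExcitationModel",
    "build_toy_system",
    "build_toy_potential",
    "make_refined_variant",
    "generate_excitations",
    "torsion_coordinate",
    "torsion_energy_profile",
    "rigid_rotor_modes",
    "TORSION_INDICES",
    "MARKER_PAIR",
    "RING_BOND",
    "ROTOR_ATOMS",
]

#: dihedral defining the rotor torsion angle theta (ring-M-N-marker)
TORSION_INDICES = (1, 0, 5, 6)
#: the two marker atoms whose distance is the rotor "width"
MARKER_PAIR = (6, 7)
#: the ring bond whose equilibrium length the refined variant shifts
RING_BOND = (1, 2)
#: atoms that rotate about the M-N axis
ROTOR_ATOMS = [5, 6, 7]


@dataclass
class ToyChromophoreSpec:
    """Parameters of the toy chromophore.

    The torsion potential is sum_m (k_m/2)(1 + cos(n_m theta - gamma_m));
    the default coefficients place minima near -90/0/+90 deg with the
    central minimum deepest and the -90 deg well slightly below the +90 deg
    one, giving room-temperature conformer abundances of roughly 15/75/10
    (A/B/A').  ``torsion_scale`` multiplies all torsion coefficients, which
    tunes the torsional frequency (scale ~0.01 brings it into the
    few-cm^-1 regime of an almost perfectly free rotor).
    """

    central_mass: float = 100.0
    marker_width: float = 4.2  # A, equilibrium distance between the markers
    torsion_scale: float = 1.0
    #: scales the chromophore's charges and LJ well depths; 0 isolates the
    #: bonded torsion profile (the nonbonded tails otherwise stiffen the
    #: nearly free rotor noticeably once the barrier is scaled far down)
    nonbonded_scale: float = 1.0
    # (barrier eV, periodicity, phase deg); see class docstring
    torsion_terms: tuple[tuple[float, int, float], ...] = (
        (0.084, 1, 180.0),
        (0.006, 2, 180.0),
        (0.028, 3, 180.0),
        (0.018, 4, 180.0),
        (0.018, 1, 90.0),
    )
    bond_k: float = 25.0  # eV/A^2
    angle_k: float = 4.0  # eV/rad^2
    charges: tuple[float, ...] = (0.4, -0.05, -0.05, -0.05, -0.05, -0.3, 0.05, 0.05)


@dataclass
class ToyExcitationModel:
    """Linear-plus-noise map from geometries to vertical excitations.

    Each state i has E_gi = E0_i + sum_k c_ik (x_k(g) - x_k_ref) + noise and
    a fixed base oscillator strength.  ``couplings`` maps a state index to a
    list of (coordinate, coefficient, reference value); coefficients are in
    eV per coordinate unit (A or deg).
    """

    base_energies: tuple[float, ...] = (3.0, 4.9, 5.5)
    base_strengths: tuple[float, ...] = (0.5, 0.8, 0.2)
    couplings: dict = field(default_factory=dict)
    noise_sigma: float = 0.0

    @classmethod
    def ring_bond_model(
        cls, coefficient: float = -5.0, reference: float | None = None, noise_sigma: float = 0.05
    ) -> "ToyExcitationModel":
        """Default model: the lowest state couples to the ring bond length.

        With the default coefficient of -5 eV/A, shortening the ring bond by
        0.04 A (the refined-potential shift) moves the first band up by
        0.2 eV — the analytically predictable blue shift used in end-to-end
        checks.
        """
        coord = InternalCoordinate("distance", RING_BOND, "ring-bond")
        if reference is None:
            reference = _reference_geometry()[1]  # equilibrium ring-bond length
        return cls(
            couplings={0: [(coord, coefficient, reference)]},
            noise_sigma=noise_sigma,
        )


def _reference_geometry() -> tuple[np.ndarray, float]:
    """Reference coordinates of the isolated chromophore (conformer B).

    The rotor axis M-N lies along -x; the ring is attached 120 deg away from
    it (a bent skeleton, so every out-of-plane motion is restrained at first
    order by dihedral terms), extending in the +x/+y quadrant.  The two
    markers straddle the rotor axis symmetrically, 4.2 A apart.
    """
    u = np.array([0.5, np.sqrt(3.0) / 2.0, 0.0])  # ring axis direction
    v = np.array([-np.sqrt(3.0) / 2.0, 0.5, 0.0])  # in-plane perpendicular
    r1 = 2.0 * u
    positions = np.array(
        [
            [0.0, 0.0, 0.0],  # M
            r1,  # R1
            r1 + 1.1 * u + 1.15 * v,  # R2
            r1 + 1.1 * u - 1.15 * v,  # R3
            r1 + 2.2 * u,  # R4
            [-2.1, 0.0, 0.0],  # N (rotor anchor)
            [-2.8, 2.1, 0.0],  # H1 (marker)
            [-2.8, -2.1, 0.0],  # H2 (marker)
        ]
    )
    ring_bond_length = float(np.linalg.norm(positions[2] - positions[1]))
    return positions, ring_bond_length


def _chromophore_terms(spec: ToyChromophoreSpec, positions: np.ndarray):
    """Bond/angle/torsion term lists with equilibria taken from the geometry."""

    def dist(i, j):
        return float(np.linalg.norm(positions[j] - positions[i]))

    def ang(i, j, k):
        return evaluate_internal(InternalCoordinate("angle", (i, j, k)), positions)

    bk = spec.bond_k
    bonds = [
        BondTerm(0, 1, 20.0, dist(0, 1)),
        BondTerm(1, 2, bk, dist(1, 2)),
        BondTerm(1, 3, bk, dist(1, 3)),
        BondTerm(2, 4, bk, dist(2, 4)),
        BondTerm(3, 4, bk, dist(3, 4)),
        BondTerm(0, 5, 15.0, dist(0, 5)),
        BondTerm(5, 6, 12.0, dist(5, 6)),
        BondTerm(5, 7, 12.0, dist(5, 7)),
    ]
    ak = spec.angle_k
    angles = [
        AngleTerm(0, 1, 2, ak, ang(0, 1, 2)),
        AngleTerm(0, 1, 3, ak, ang(0, 1, 3)),
        AngleTerm(1, 2, 4, ak, ang(1, 2, 4)),
        AngleTerm(1, 3, 4, ak, ang(1, 3, 4)),
        AngleTerm(2, 4, 3, ak, ang(2, 4, 3)),
        AngleTerm(1, 0, 5, ak, ang(1, 0, 5)),  # skeleton bend (in-plane swing)
        AngleTerm(0, 5, 6, 3.0, ang(0, 5, 6)),
        AngleTerm(0, 5, 7, 3.0, ang(0, 5, 7)),
        AngleTerm(6, 5, 7, 3.0, ang(6, 5, 7)),
    ]

    def improper(i, j, k_, l, barrier):
        """n=2 cosine term whose minimum sits at the reference dihedral."""
        phi0 = evaluate_internal(InternalCoordinate("dihedral", (i, j, k_, l)), positions)
        gamma = (2.0 * phi0 - 180.0) % 360.0
        return TorsionTerm(i, j, k_, l, terms=((barrier, 2, gamma),))

    scale = spec.torsion_scale
    rotor_terms = tuple((k * scale, n, g) for k, n, g in spec.torsion_terms)
    torsions = [
        TorsionTerm(*TORSION_INDICES, terms=rotor_terms),
        # out-of-plane stiffeners: ring planarity, ring-spin/rotor-swing
        # impropers across the bent skeleton, and the marker-wag improper
        # (invariant under the rotor spin, so the torsion profile is pure)
        improper(0, 1, 2, 4, 0.8),
        improper(0, 1, 3, 4, 0.8),
        improper(2, 1, 0, 5, 3.0),
        improper(3, 1, 0, 5, 3.0),
        improper(6, 5, 0, 7, 2.5),
    ]
    return bonds, angles, torsions


def build_toy_system(
    spec: ToyChromophoreSpec | None = None,
    n_solvent: int = 0,
    droplet_radius: float = 12.0,
    temperature: float = 300.0,
    seed: int | None = None,
) -> tuple[MolecularSystem, Snapshot]:
    """Toy chromophore, optionally embedded in an LJ solvent droplet.

    Solvent particles are placed by rejection sampling inside the droplet
    with a 2.5 A minimum separation from all previously placed atoms;
    initial velocities are Maxwell-Boltzmann at ``temperature``.  The same
    seed reproduces the system bit-identically.
    """
    if spec is None:
        spec = ToyChromophoreSpec()
    if n_solvent < 0:
        raise ValueError("n_solvent must be >= 0")
    rng = np.random.default_rng(seed)
    positions, _ = _reference_geometry()
    bonds, angles, torsions = _chromophore_terms(spec, positions)

    symbols = ["M", "C", "C", "C", "C", "N", "H", "H"]
    masses = [spec.central_mass, 12.011, 12.011, 12.011, 12.011, 14.007, 1.008, 1.008]
    charges = [q * spec.nonbonded_scale for q in spec.charges]
    eps = [e * spec.nonbonded_scale
           for e in (0.008, 0.004, 0.004, 0.004, 0.004, 0.007, 0.001, 0.001)]
    sig = [3.2, 3.4, 3.4, 3.4, 3.4, 3.3, 2.0, 2.0]
    groups = ["solute"] * 8

    coords = [positions]
    min_sep = 2.5
    placed = positions.copy()
    max_tries = 20000
    solvent_coords = []
    for _ in range(n_solvent):
        for attempt in range(max_tries):
            u = rng.random(3)
            # uniform in sphere of radius (droplet_radius - 1)
            radius = (droplet_radius - 1.0) * u[0] ** (1.0 / 3.0)
            cos_t = 2.0 * u[1] - 1.0
            sin_t = np.sqrt(1.0 - cos_t**2)
            phi = 2.0 * np.pi * u[2]
            cand = radius * np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
            if np.min(np.linalg.norm(placed - cand, axis=1)) >= min_sep:
                solvent_coords.append(cand)
                placed = np.vstack([placed, cand])
                break
        else:
            raise ValueError(
                f"droplet radius {droplet_radius} A too small to pack {n_solvent} solvent particles"
            )
    if solvent_coords:
        coords.append(np.array(solvent_coords))
        symbols += ["W"] * n_solvent
        masses += [18.015] * n_solvent
        charges += [0.0] * n_solvent
        eps += [0.0065] * n_solvent
        sig += [3.15] * n_solvent
        groups += ["environment"] * n_solvent

    all_positions = np.vstack(coords)
    system = MolecularSystem(
        symbols=symbols,
        masses=np.array(masses),
        charges=np.array(charges),
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        lj_epsilon=np.array(eps),
        lj_sigma=np.array(sig),
        groups=groups,
    )
    velocities = maxwell_boltzmann_velocities(system.masses, temperature, rng, remove_com=True)
    snapshot = Snapshot(positions=all_positions, velocities=velocities, stage="initial")
    snapshot.meta["build_seed"] = seed
    return system, snapshot


def build_toy_potential(
    system: MolecularSystem,
    droplet_radius: float | None = None,
    wall_k: float = 0.5,
    cutoff: float = 10.0,
) -> PotentialModel:
    """Potential for a toy system, with droplet confinement if requested."""
    wall = Wall(force_constant=wall_k, radius=droplet_radius) if droplet_radius else None
    return PotentialModel(system, cutoff=cutoff, wall=wall)


def make_refined_variant(system: MolecularSystem, shifts: dict | None = None) -> MolecularSystem:
    """Copy of the system with shifted equilibrium bond lengths / angles.

    ``shifts`` maps ``("bond", (i, j))`` to a delta r0 in A and
    ``("angle", (i, j, k))`` to a delta theta0 in degrees.  The default
    shortens the designated ring bond by 0.04 A — the typical size of a
    generic-force-field bond-length bias relative to a higher-level
    potential.  Topology is unchanged.
    """
    if shifts is None:
        shifts = {("bond", RING_BOND): -0.04}
    refined = system.copy()
    for (kind, atoms), delta in shifts.items():
        atoms = tuple(atoms)
        if kind == "bond":
            hits = [
                b for b in refined.bonds if (b.i, b.j) == atoms or (b.j, b.i) == atoms
            ]
            if not hits:
                raise KeyError(f"no bond term between atoms {atoms}")
            refined.bonds = [
                replace(b, r0=b.r0 + delta) if b in hits else b for b in refined.bonds
            ]
        elif kind == "angle":
            hits = [
                a
                for a in refined.angles
                if (a.i, a.j, a.k) == atoms or (a.k, a.j, a.i) == atoms
            ]
            if not hits:
                raise KeyError(f"no angle term over atoms {atoms}")
            refined.angles = [
                replace(a, theta0=a.theta0 + delta) if a in hits else a
                for a in refined.angles
            ]
        else:
            raise KeyError(f"unknown term kind {kind!r}")
    return refined


def torsion_coordinate() -> InternalCoordinate:
    return InternalCoordinate("dihedral", TORSION_INDICES, "theta")


def torsion_energy_profile(
    potential: PotentialModel,
    reference_positions: np.ndarray,
    angles_deg: np.ndarray,
) -> np.ndarray:
    """Potential energy along a rigid rotation of the rotor about the M-N axis.

    Returns energies (eV) relative to the profile minimum; this is the
    effective one-dimensional torsion profile used for analytic Boltzmann
    occupancies of the conformer wells.
    """
    reference = np.asarray(reference_positions, dtype=float)
    theta0 = evaluate_internal(torsion_coordinate(), reference)
    axis = reference[5] - reference[0]
    axis = axis / np.linalg.norm(axis)
    origin = reference[0]
    energies = np.empty(len(angles_deg))
    for k, target in enumerate(np.asarray(angles_deg, dtype=float)):
        ang = np.radians(target - theta0)
        pos = reference.copy()
        rel = pos[ROTOR_ATOMS] - origin
        cos, sin = np.cos(ang), np.sin(ang)
        rot = (
            rel * cos
            + np.cross(np.broadcast_to(axis, rel.shape), rel) * sin
            + np.outer(rel @ axis, axis) * (1.0 - cos)
        )
        pos[ROTOR_ATOMS] = origin + rot
        energies[k] = potential.energy(pos)
    return energies - energies.min()


def conformer_boltzmann_weights(
    potential: PotentialModel,
    reference_positions: np.ndarray,
    temperature: float = 300.0,
    n_grid: int = 720,
) -> dict[str, float]:
    """Analytic Boltzmann occupancies of the A / B / A' bands.

    Integrates exp(-V(theta)/kT) over the conformer bands of the rigid
    torsion profile (A: [-135, -45], B: (-45, 45), A': [45, 135]; the
    wraparound region is split between A and A' by sign).
    """
    grid = np.linspace(-180.0, 180.0, n_grid, endpoint=False)
    energies = torsion_energy_profile(potential, reference_positions, grid)
    weights = np.exp(-energies / (KB * temperature))
    from .analysis import classify_conformer

    out = {"A": 0.0, "B": 0.0, "A'": 0.0}
    for theta, w in zip(grid, weights):
        out[classify_conformer(theta)] += float(w)
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def rigid_rotor_modes(
    system: MolecularSystem,
    reference_positions: np.ndarray,
    wavenumber_cm: float = 8.0,
) -> NormalModeSet:
    """Idealized single-mode set: the pure torsion as a *linear* normal mode.

    The mode vector displaces only the two marker atoms, along straight
    lines perpendicular to the rotor plane (the tangents of their rotation
    circles at the reference geometry) — exactly the linearization a
    harmonic normal-mode analysis produces for a free rotor.  Displacing
    along this vector shears the rotor, which is the point of the fixture.
    """
    reference = np.asarray(reference_positions, dtype=float)
    n = system.n_atoms
    mode = np.zeros((n, 3))
    axis = reference[5] - reference[0]
    axis = axis / np.linalg.norm(axis)
    for atom in MARKER_PAIR:
        rel = reference[atom] - reference[0]
        tangent = np.cross(axis, rel)
        mode[atom] = tangent * np.sqrt(system.masses[atom])
    mode /= np.linalg.norm(mode)
    return NormalModeSet(
        reference=reference,
        masses=system.masses.copy(),
        wavenumbers=np.array([wavenumber_cm]),
        modes=mode[None],
        symbols=list(system.symbols),
        n_rigid_removed=3 * n - 1,
    )


def generate_excitations(
    model: ToyExcitationModel,
    snapshots: list[Snapshot],
    seed: int | None = None,
) -> list[ExcitationTable]:
    """Excitation tables for an ensemble under the linear toy model."""
    rng = np.random.default_rng(seed)
    tables = []
    for g, snap in enumerate(snapshots):
        energies = np.array(model.base_energies, dtype=float)
        for state, terms in model.couplings.items():
            for coord, coeff, ref in terms:
                energies[state] += coeff * (evaluate_internal(coord, snap) - ref)
        if model.noise_sigma > 0:
            energies = energies + rng.normal(0.0, model.noise_sigma, energies.size)
        if np.any(energies <= 0):
            raise ValueError(
                "excitation model produced non-positive energies; rescale the model"
            )
        tables.append(
            ExcitationTable(
                geometry_id=f"g{g:05d}",
                energies=energies,
                strengths=np.array(model.base_strengths, dtype=float),
            )
        )
    return tables
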