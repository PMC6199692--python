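"""Harmonic analysis: finite-difference Hessians, normal modes, Molden I/O.

The Hessian is built from central differences of the analytic forces,
mass-weighted, and the six rigid-body directions (Eckart translation and
rotation vectors at the reference geometry) are projected out before
diagonalization.  Frequencies are reported as wavenumbers in cm^-1;
imaginary frequencies are flagged and carried as negative wavenumbers,
never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forcefield import PotentialModel
from .units import BOHR_TO_A, EV_TO_AMU_A2_FS2, wavenumber_from_omega, zpe_from_wavenumber
from .system import ATOMIC_MASSES

__all__ = ["NormalModeSet", "compute_normal_modes", "read_molden", "write_molden"]


class NotAtMinimumError(ValueError):
    """Gradient at the supplied geometry is above tolerance."""


@dataclass
class NormalModeSet:
    """Reference geometry plus mass-weighted orthonormal vibrational modes.

    ``modes[k]`` is the (n_atoms, 3) mass-weighted displacement pattern of
    mode ``k``; Cartesian displacement per unit normal coordinate is
    ``modes[k] / sqrt(m)``.  ``wavenumbers`` are sorted ascending with
    imaginary modes stored as negative values and listed in
    ``imaginary_modes``.
    """

    reference: np.ndarray  # (n_atoms, 3), A
    masses: np.ndarray  # amu
    wavenumbers: np.ndarray  # cm^-1; negative = imaginary
    modes: np.ndarray  # (n_modes, n_atoms, 3), mass-weighted, orthonormal
    symbols: list[str] = field(default_factory=list)
    n_rigid_removed: int = 6

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.reference.shape[0]

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def imaginary_modes(self) -> list[int]:
        return [int(i) for i in np.where(self.wavenumbers < 0.0)[0]]

    def zpe_per_mode(self) -> np.ndarray:
        """Zero-point energies (eV); imaginary modes contribute zero."""
        return np.where(self.wavenumbers > 0, zpe_from_wavenumber(np.abs(self.wavenumbers)), 0.0)

    def total_zpe(self, exclude: set[int] | None = None) -> float:
        zpe = self.zpe_per_mode()
        if exclude:
            zpe = np.array([z for i, z in enumerate(zpe) if i not in exclude])
        return float(zpe.sum())

    def orthonormality_residual(self) -> float:
        flat = self.modes.reshape(self.n_modes, -1)
        return float(np.abs(flat @ flat.T - np.eye(self.n_modes)).max())


def rigid_body_vectors(reference: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation+rotation vectors (Eckart frame)."""
    n = reference.shape[0]
    sqm = np.sqrt(masses)
    com = (masses[:, None] * reference).sum(axis=0) / masses.sum()
    x = reference - com
    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = sqm
        vecs.append(t.ravel())
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, (n, 3)), x) * sqm[:, None]
        vecs.append(r.ravel())
    basis = np.array(vecs).T  # (3n, 6)
    q, rmat = np.linalg.qr(basis)
    keep = np.abs(np.diag(rmat)) > 1e-10  # drop rank-deficient (linear) rotations
    return q[:, keep]


def compute_normal_modes(
    potential: PotentialModel,
    minimum_positions: np.ndarray,
    displacement_step: float = 0.005,
    gradient_tolerance: float = 5e-4,
    imaginary_tolerance_cm: float = 5.0,
) -> NormalModeSet:
    """Finite-difference normal modes at a minimum of the toy potential.

    Raises :class:`NotAtMinimumError` if the gradient norm per atom exceeds
    ``gradient_tolerance`` (eV/A).  Negative Hessian eigenvalues beyond
    ``imaginary_tolerance_cm`` are flagged as imaginary (negative
    wavenumbers) with a warning.
    """
    r0 = np.asarray(minimum_positions, dtype=float).copy()
    masses = potential.system.masses
    n = r0.shape[0]
    _, f0 = potential.energy_forces(r0)
    gmax = float(np.abs(f0).max())
    if gmax > gradient_tolerance:
        raise NotAtMinimumError(
            f"max gradient component {gmax:.2e} eV/A exceeds {gradient_tolerance:.0e}"
        )

    h = displacement_step
    hess = np.zeros((3 * n, 3 * n))
    r = r0.copy()
    for a in range(n):
        for c in range(3):
            k = 3 * a + c
            r[a, c] = r0[a, c] + h
            _, fp = potential.energy_forces(r)
            r[a, c] = r0[a, c] - h
            _, fm = potential.energy_forces(r)
            r[a, c] = r0[a, c]
            hess[:, k] = -(fp - fm).ravel() / (2 * h)
    hess = 0.5 * (hess + hess.T)

    sqm = np.repeat(np.sqrt(masses), 3)
    hmw = hess / np.outer(sqm, sqm)

    rigid = rigid_body_vectors(r0, masses)
    proj = np.eye(3 * n) - rigid @ rigid.T
    hproj = proj @ hmw @ proj

    evals, evecs = np.linalg.eigh(hproj)
    # identify and drop the projected-out rigid-body space by overlap
    overlaps = np.linalg.norm(rigid.T @ evecs, axis=0)
    vib = overlaps < 0.5
    evals = evals[vib]
    evecs = evecs[:, vib]
    order = np.argsort(evals)
    evals = evals[order]
    evecs = evecs[:, order]

    omega_sq = evals * EV_TO_AMU_A2_FS2  # fs^-2
    wavenumbers = np.sign(omega_sq) * wavenumber_from_omega(np.sqrt(np.abs(omega_sq)))
    imag = wavenumbers < -imaginary_tolerance_cm
    if np.any(imag):
        warnings.warn(
            f"{int(imag.sum())} imaginary frequencies found "
            f"(lowest {wavenumbers.min():.1f} cm^-1)",
            stacklevel=2,
        )
    # wavenumbers in [-tol, 0) are numerically zero-ish artifacts; clip to tiny positive
    small = (wavenumbers < 0) & ~imag
    wavenumbers[small] = np.abs(wavenumbers[small])

    modes = evecs.T.reshape(-1, n, 3)
    return NormalModeSet(
        reference=r0,
        masses=masses.copy(),
        wavenumbers=wavenumbers,
        modes=modes,
        symbols=list(potential.system.symbols),
        n_rigid_removed=rigid.shape[1],
    )


# --------------------------------------------------------------------- Molden

def write_molden(path, modes: NormalModeSet) -> None:
    """Write a Molden frequency file ([FR-COORD]/[FREQ]/[FR-NORM-COORD]).

    Coordinates and displacement vectors are written in bohr per the Molden
    standard; displacements are the Cartesian (not mass-weighted) patterns.
    """
    cart = modes.modes / np.sqrt(modes.masses)[None, :, None]
    with open(path, "w") as fh:
        fh.write("[Molden Format]\n[FR-COORD]\n")
        for sym, xyz in zip(modes.symbols, modes.reference / BOHR_TO_A):
            fh.write(f" {sym:<3s} {xyz[0]:16.10f} {xyz[1]:16.10f} {xyz[2]:16.10f}\n")
        fh.write("[FREQ]\n")
        for w in modes.wavenumbers:
            fh.write(f" {w:14.6f}\n")
        fh.write("[FR-NORM-COORD]\n")
        for k in range(modes.n_modes):
            fh.write(f" vibration {k + 1}\n")
            for xyz in cart[k] / BOHR_TO_A:
                fh.write(f" {xyz[0]:16.10f} {xyz[1]:16.10f} {xyz[2]:16.10f}\n")


def read_molden(path, masses: np.ndarray | None = None) -> NormalModeSet:
    """Read a Molden frequency file into a :class:`NormalModeSet`.

    Units are converted from bohr; the displacement vectors are mass-weighted
    and re-orthonormalized (a warning is emitted if the adjustment is larger
    than 1e-3, which indicates modes inconsistent with the masses used).
    """
    with open(path) as fh:
        text = fh.read()
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("["):
            current = stripped.strip("[]").upper()
            sections[current] = []
        elif current is not None and stripped:
            sections[current].append(stripped)

    for required in ("FR-COORD", "FREQ", "FR-NORM-COORD"):
        if required not in sections:
            raise ValueError(f"Molden file missing [{required}] section")

    symbols: list[str] = []
    coords: list[list[float]] = []
    for line in sections["FR-COORD"]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    reference = np.array(coords) * BOHR_TO_A
    n = len(symbols)

    freqs = np.array([float(ln.split()[0]) for ln in sections["FREQ"]])

    disp_rows: list[list[float]] = []
    for line in sections["FR-NORM-COORD"]:
        if line.lower().startswith("vibration"):
            continue
        disp_rows.append([float(v) for v in line.split()[:3]])
    if len(disp_rows) != len(freqs) * n:
        raise ValueError(
            "atom count mismatch between [FR-COORD] and [FR-NORM-COORD] sections"
        )
    cart = np.array(disp_rows).reshape(len(freqs), n, 3) * BOHR_TO_A

    if masses is None:
        try:
            masses = np.array([ATOMIC_MASSES[s] for s in symbols])
        except KeyError as exc:
            raise ValueError(f"unknown element {exc}; supply masses explicitly") from exc
    masses = np.asarray(masses, dtype=float)

    mw = cart * np.sqrt(masses)[None, :, None]
    flat = mw.reshape(len(freqs), -1)
    norms = np.linalg.norm(flat, axis=1)
    flat = flat / norms[:, None]
    # re-orthonormalize (Gram-Schmidt via QR on the transpose)
    q, _ = np.linalg.qr(flat.T)
    adjusted = q.T[: len(freqs)]
    # align signs with the input modes
    signs = np.sign(np.einsum("ij,ij->i", adjusted, flat))
    signs[signs == 0] = 1.0
    adjusted = adjusted * signs[:, None]
    drift = float(np.abs(adjusted - flat).max())
    if drift > 1e-3:
        warnings.warn(f"modes re-orthonormalized; max adjustment {drift:.1e}", stacklevel=2)

    return NormalModeSet(
        reference=reference,
        masses=masses,
        wavenumbers=freqs,
        modes=adjusted.reshape(len(freqs), n, 3),
        symbols=symbols,
        n_rigid_removed=3 * n - len(freqs),
    )
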