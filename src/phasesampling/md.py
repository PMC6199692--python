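"""Minimal MD engine: velocity Verlet / leapfrog, thermostats, freezing.

Conventions
-----------
* Accelerations are ``F / m`` converted to A/fs^2 (forces in eV/A, masses in
  amu).
* Frozen atoms are excluded from force application, velocity updates,
  thermostat kinetic-energy bookkeeping and temperature DOF counts; their
  interactions still act on mobile atoms.
* NVT uses stochastic velocity rescaling (canonical sampling through velocity
  rescaling, CSVR) by default, which reproduces the canonical kinetic-energy
  *distribution* — important because kinetic-energy histograms are an
  analysis target — with simple Berendsen rescaling available for rough
  thermalization.
* Leapfrog trajectories store velocities at half steps, v(t - dt/2); this
  convention is recorded in the trajectory metadata and can be undone with
  :func:`phasesampling.protocols.leapfrog_to_verlet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import PotentialModel
from .system import Snapshot
from .units import AMU_A2_FS2_TO_EV, EV_TO_AMU_A2_FS2, KB

__all__ = [
    "MDConfig",
    "ThermostatConfig",
    "Trajectory",
    "IntegrationUnstableError",
    "propagate",
    "instantaneous_temperature",
    "maxwell_boltzmann_velocities",
]

ACC = EV_TO_AMU_A2_FS2  # (eV/A)/amu -> A/fs^2


class IntegrationUnstableError(RuntimeError):
    """Raised when the integrator detects an exploding trajectory."""

    def __init__(self, step: int, message: str) -> None:
        super().__init__(f"integration unstable at step {step}: {message}")
        self.step = step


@dataclass
class ThermostatConfig:
    """Target temperature (K), coupling time (fs), scheme, atom selection.

    ``selection=None`` thermostats every mobile atom.  Schemes:

    * ``"csvr"`` — stochastic velocity rescaling; canonical for the *total*
      kinetic energy, but the global factor cannot redistribute energy
      between modes, so a quasi-harmonic molecule equilibrates only through
      its weak anharmonic couplings (slow).
    * ``"langevin"`` — per-DOF Ornstein-Uhlenbeck friction+noise with
      gamma = 1/coupling time; thermalizes every mode directly (the choice
      for local reheating, where per-mode equilibration is the point).
    * ``"berendsen"`` — weak-coupling rescaling; not canonical, offered for
      rough thermalization only.
    """

    temperature: float
    coupling_time_fs: float = 50.0
    scheme: str = "csvr"
    selection: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.scheme not in ("csvr", "langevin", "berendsen"):
            raise ValueError(f"unknown thermostat scheme {self.scheme!r}")


@dataclass
class MDConfig:
    """Integration parameters for one run."""

    dt: float = 0.5  # fs
    n_steps: int = 1000
    integrator: str = "velocity-verlet"
    ensemble: str = "NVE"
    frozen: frozenset[int] = frozenset()
    seed: int | None = None
    stride: int = 1  # record every ``stride`` steps
    max_step_displacement: float = 1.0  # A; larger per-step moves abort

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.integrator not in ("velocity-verlet", "leapfrog"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.ensemble not in ("NVE", "NVT"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")


@dataclass
class Trajectory:
    """Recorded frames of one propagation."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_atoms, 3)
    velocities: np.ndarray
    energies: np.ndarray  # potential energy per frame, eV
    kinetic: np.ndarray  # kinetic energy per frame, eV
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, index: int, stage: str = "production") -> Snapshot:
        return Snapshot(
            positions=self.positions[index].copy(),
            velocities=self.velocities[index].copy(),
            time_fs=float(self.times[index]),
            stage=stage,
        )

    def snapshots(self, stage: str = "production") -> list[Snapshot]:
        return [self.frame(i, stage) for i in range(self.n_frames)]

    @property
    def total_energy(self) -> np.ndarray:
        return self.energies + self.kinetic


def instantaneous_temperature(
    snapshot: Snapshot,
    masses: np.ndarray,
    selection: np.ndarray | None = None,
    n_removed_dof: int = 0,
) -> float:
    """Kinetic temperature T = 2 E_kin / (n_dof k_B) over a selection."""
    masses = np.asarray(masses, dtype=float)
    if selection is None:
        selection = np.arange(snapshot.n_atoms)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection for temperature")
    v = snapshot.velocities[selection]
    m = masses[selection]
    ekin = 0.5 * float(np.sum(m * np.einsum("ij,ij->i", v, v))) * AMU_A2_FS2_TO_EV
    n_dof = 3 * selection.size - n_removed_dof
    if n_dof <= 0:
        raise ValueError("no degrees of freedom left after removal")
    return 2.0 * ekin / (n_dof * KB)


def maxwell_boltzmann_velocities(
    masses: np.ndarray,
    temperature: float,
    rng: np.random.Generator,
    remove_com: bool = False,
) -> np.ndarray:
    """Draw velocities (A/fs) from the Maxwell-Boltzmann distribution."""
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * temperature * EV_TO_AMU_A2_FS2 / masses)
    v = rng.normal(size=(masses.size, 3)) * sigma[:, None]
    if remove_com:
        p = (masses[:, None] * v).sum(axis=0)
        v -= p / masses.sum()
    return v


def _kinetic_energy(v: np.ndarray, m: np.ndarray) -> float:
    return 0.5 * float(np.sum(m * np.einsum("ij,ij->i", v, v))) * AMU_A2_FS2_TO_EV


def _csvr_factor(
    ekin: float, target: float, n_dof: int, dt: float, tau: float, rng: np.random.Generator
) -> float:
    """Stochastic velocity rescaling factor (canonical sampling)."""
    if ekin <= 0.0:
        return 1.0
    c = math.exp(-dt / tau)
    r1 = rng.normal()
    sum_sq = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
    ratio = target / (n_dof * ekin)
    alpha_sq = (
        c
        + (1.0 - c) * ratio * (r1**2 + sum_sq)
        + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
    )
    return math.sqrt(max(alpha_sq, 0.0))


def _apply_thermostat(
    v: np.ndarray,
    masses: np.ndarray,
    thermostat: ThermostatConfig,
    sel: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> None:
    if thermostat.scheme == "langevin":
        c1 = math.exp(-dt / thermostat.coupling_time_fs)
        sigma = np.sqrt(
            (1.0 - c1**2) * KB * thermostat.temperature * EV_TO_AMU_A2_FS2 / masses[sel]
        )
        v[sel] = c1 * v[sel] + sigma[:, None] * rng.normal(size=(sel.size, 3))
        return
    n_dof = 3 * sel.size
    ekin = _kinetic_energy(v[sel], masses[sel])
    target = 0.5 * n_dof * KB * thermostat.temperature
    if thermostat.scheme == "csvr":
        lam = _csvr_factor(ekin, target, n_dof, dt, thermostat.coupling_time_fs, rng)
    else:  # berendsen
        if ekin <= 0:
            return
        t_now = 2.0 * ekin / (n_dof * KB)
        lam = math.sqrt(
            max(1.0 + dt / thermostat.coupling_time_fs * (thermostat.temperature / max(t_now, 1e-12) - 1.0), 0.0)
        )
    v[sel] *= lam


def propagate(
    potential: PotentialModel,
    snapshot: Snapshot,
    config: MDConfig,
    thermostat: ThermostatConfig | None = None,
) -> Trajectory:
    """Integrate the equations of motion; returns the recorded trajectory.

    The returned trajectory includes the initial frame.  For leapfrog runs
    the recorded velocities are the half-step values v(t - dt/2) and
    ``meta["velocity_convention"]`` says so.
    """
    sysm = potential.system
    masses = sysm.masses
    n = sysm.n_atoms
    if snapshot.n_atoms != n:
        raise ValueError("snapshot does not match system atom count")
    if config.ensemble == "NVT" and thermostat is None:
        raise ValueError("NVT requested but no thermostat given")
    if config.ensemble == "NVE":
        thermostat = None
    if thermostat is not None and thermostat.coupling_time_fs <= config.dt:
        raise ValueError("thermostat coupling time must exceed the time step")

    frozen = sorted(set(config.frozen) | set(sysm.frozen))
    mobile_mask = np.ones(n, dtype=bool)
    if frozen:
        mobile_mask[frozen] = False
    if thermostat is not None:
        sel = (
            np.asarray(thermostat.selection, dtype=int)
            if thermostat.selection is not None
            else np.where(mobile_mask)[0]
        )
        sel = sel[mobile_mask[sel]]
        if sel.size == 0:
            raise ValueError("thermostat selection contains no mobile atoms")
    else:
        sel = None

    rng = np.random.default_rng(config.seed)
    dt = config.dt
    r = snapshot.positions.copy()
    v = snapshot.velocities.copy()
    v[~mobile_mask] = 0.0

    energy, forces = potential.energy_forces(r)
    a = forces * ACC / masses[:, None]
    a[~mobile_mask] = 0.0

    leapfrog = config.integrator == "leapfrog"
    if leapfrog:
        # bootstrap half-step velocity from the synchronous input snapshot;
        # v_lag trails by one step so recorded frames pair R(t) with
        # v(t - dt/2), the convention leapfrog restart files use
        v_half = v + 0.5 * dt * a
        v_half[~mobile_mask] = 0.0
        v_lag = v.copy()

    n_rec = config.n_steps // config.stride + 1
    times = np.empty(n_rec)
    rpos = np.empty((n_rec, n, 3))
    rvel = np.empty((n_rec, n, 3))
    epot = np.empty(n_rec)
    ekin = np.empty(n_rec)

    def record(idx: int, step: int) -> None:
        times[idx] = snapshot.time_fs + step * dt
        rpos[idx] = r
        vel = v_lag if leapfrog else v
        rvel[idx] = vel
        epot[idx] = energy
        ekin[idx] = _kinetic_energy(vel[mobile_mask], masses[mobile_mask])

    record(0, 0)
    rec = 1
    for step in range(1, config.n_steps + 1):
        if leapfrog:
            dr = dt * v_half
        else:
            v += 0.5 * dt * a
            v[~mobile_mask] = 0.0
            dr = dt * v
        max_disp = float(np.abs(dr).max()) if dr.size else 0.0
        if max_disp > config.max_step_displacement:
            raise IntegrationUnstableError(step, f"per-step displacement {max_disp:.2f} A")
        r = r + dr
        if frozen:
            r[frozen] = snapshot.positions[frozen]
        energy, forces = potential.energy_forces(r)
        if not np.isfinite(energy):
            raise IntegrationUnstableError(step, "non-finite potential energy")
        a = forces * ACC / masses[:, None]
        a[~mobile_mask] = 0.0
        if leapfrog:
            v_lag = v_half.copy()  # v(t - dt/2) for the frame at time t
            v_half = v_half + dt * a
            v_half[~mobile_mask] = 0.0
            if sel is not None:
                _apply_thermostat(v_half, masses, thermostat, sel, dt, rng)
        else:
            v += 0.5 * dt * a
            v[~mobile_mask] = 0.0
            if sel is not None:
                _apply_thermostat(v, masses, thermostat, sel, dt, rng)
        if step % config.stride == 0:
            record(rec, step)
            rec += 1

    meta = {
        "integrator": config.integrator,
        "ensemble": config.ensemble,
        "dt_fs": dt,
        "velocity_convention": "half-step" if leapfrog else "on-step",
        "frozen": list(frozen),
        "seed": config.seed,
    }
    return Trajectory(times[:rec], rpos[:rec], rvel[:rec], epot[:rec], ekin[:rec], meta)
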