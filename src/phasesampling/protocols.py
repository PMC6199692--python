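"""Post-processing protocols for MD-sampled snapshots.

Two protocols correct known deficiencies of force-field MD sampling when the
ensemble is meant to feed excited-state dynamics or spectrum simulations:

* **local temperature adjustment** — a classical 300 K trajectory gives every
  mode ~k_B T of energy, far below the molecular zero-point energy.  The
  protocol freezes the environment and re-thermostats only the solute at a
  higher temperature whose classical energy matches the ZPE, then restores
  the environment velocities from the production snapshot.
* **individual refinement** — each snapshot is relaxed by a short trajectory
  under a *refined* potential (the stand-in for a higher-level QM/MM
  potential), run for a randomized duration so that the coherent oscillation
  induced by the potential switch dephases across the ensemble instead of
  biasing it.

Also provided: snapshot extraction from production trajectories, the
leapfrog-to-velocity-Verlet synchronization (half-step position correction),
and the deterministic per-snapshot seed derivation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forcefield import PotentialModel
from .md import MDConfig, ThermostatConfig, Trajectory, instantaneous_temperature, propagate
from .system import Snapshot

__all__ = [
    "ProtocolConfig",
    "LeapfrogState",
    "extract_snapshots",
    "local_temperature_adjustment",
    "re_equilibrate",
    "individual_refinement",
    "leapfrog_to_verlet",
    "derive_seed",
]


@dataclass
class ProtocolConfig:
    """Timings and temperatures of the post-processing chain."""

    snapshot_stride_fs: float = 1000.0
    heating_temperature: float = 600.0
    heating_duration_fs: float = 2000.0
    heating_coupling_fs: float = 20.0
    #: Langevin by default: reheating must equilibrate every solute mode,
    #: which global-rescaling thermostats cannot do in a quasi-harmonic
    #: molecule on the picosecond timescale of the protocol
    heating_scheme: str = "langevin"
    reequilibration_duration_fs: float = 100.0
    refinement_min_fs: float = 50.0
    refinement_max_fs: float = 100.0
    dt: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snapshot_stride_fs", "heating_duration_fs", "reequilibration_duration_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.refinement_min_fs >= self.refinement_max_fs:
            raise ValueError("refinement duration range inverted (min must be < max)")


@dataclass
class LeapfrogState:
    """Positions R(t) with half-step velocities v(t - dt/2), as stored by
    leapfrog codes in their restart files."""

    positions: np.ndarray
    velocities_half: np.ndarray
    dt: float
    time_fs: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("time step must be positive")


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-snapshot seed: SeedSequence(master, spawn_key=(index,)).

    Documented splitting rule so ensembles are reproducible under parallel
    execution; the result is bounded below 2**31.
    """
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def extract_snapshots(trajectory: Trajectory, stride_fs: float) -> list[Snapshot]:
    """Evenly spaced snapshots (positions *and* velocities) from a trajectory.

    The stride must be a multiple of the recorded frame interval.  The count
    is floor(production length / stride); snapshots are taken at stride,
    2*stride, ... after the first frame (the initial frame itself is not a
    production sample).
    """
    times = trajectory.times
    if len(times) < 2:
        raise ValueError("trajectory has fewer than two frames")
    frame_interval = float(times[1] - times[0])
    if stride_fs < frame_interval - 1e-9:
        raise ValueError(
            f"stride {stride_fs} fs is smaller than the frame interval {frame_interval} fs"
        )
    ratio = stride_fs / frame_interval
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError("stride must be a multiple of the trajectory frame interval")
    every = int(round(ratio))
    length = float(times[-1] - times[0])
    count = int(np.floor(length / stride_fs + 1e-9))
    if count == 0:
        warnings.warn("trajectory shorter than one stride; no snapshots extracted", stacklevel=2)
        return []
    snaps = []
    for k in range(1, count + 1):
        snap = trajectory.frame(k * every, stage="production")
        snap.meta["snapshot_index"] = k - 1
        snaps.append(snap)
    return snaps


def local_temperature_adjustment(
    potential: PotentialModel,
    snapshot: Snapshot,
    config: ProtocolConfig,
    seed: int | None = None,
) -> Snapshot:
    """Reheat only the solute, with the environment frozen in place.

    The environment atoms are frozen (positions bit-conserved); the solute is
    propagated NVT at ``heating_temperature`` for ``heating_duration_fs``;
    afterwards the environment velocities are reset to the values of the
    input snapshot.  The returned snapshot carries stage ``"heated"`` and
    records the solute kinetic temperature time-averaged over the final
    quarter of the heating window.
    """
    system = potential.system
    solute = system.solute
    env = system.environment
    if env.size == 0:
        warnings.warn(
            "no environment atoms: local heating degenerates to bulk reheating",
            stacklevel=2,
        )
    n_steps = max(int(round(config.heating_duration_fs / config.dt)), 1)
    md = MDConfig(
        dt=config.dt,
        n_steps=n_steps,
        ensemble="NVT",
        frozen=frozenset(int(i) for i in env) | system.frozen,
        seed=seed,
        stride=max(n_steps // 200, 1),
    )
    thermo = ThermostatConfig(
        temperature=config.heating_temperature,
        coupling_time_fs=config.heating_coupling_fs,
        scheme=config.heating_scheme,
        selection=solute,
    )
    traj = propagate(potential, snapshot, md, thermostat=thermo)

    final = traj.frame(traj.n_frames - 1)
    # environment: positions were frozen; velocities restored from input
    if env.size:
        final.velocities[env] = snapshot.velocities[env]
    q = max(traj.n_frames * 3 // 4, 1)
    temps = [
        instantaneous_temperature(traj.frame(i), system.masses, selection=solute)
        for i in range(q, traj.n_frames)
    ]
    out = final.copy(stage="heated", seed=seed)
    out.meta.update(snapshot.meta)
    out.meta["heated_solute_temperature_K"] = float(np.mean(temps))
    out.meta["heating_target_K"] = config.heating_temperature
    return out


def re_equilibrate(
    potential: PotentialModel,
    snapshot: Snapshot,
    duration_fs: float,
    dt: float = 0.5,
) -> Snapshot:
    """Let the solvent shells adapt briefly: all atoms mobile, NVE.

    No thermostat is applied so the deliberately injected solute energy is
    not drained; the droplet confinement (the potential's wall term) keeps
    the system bounded.  ``duration_fs = 0`` is the identity.
    """
    if duration_fs < 0:
        raise ValueError("duration must be >= 0")
    if duration_fs == 0:
        return snapshot.copy(stage="reequilibrated")
    n_steps = max(int(round(duration_fs / dt)), 1)
    md = MDConfig(dt=dt, n_steps=n_steps, ensemble="NVE", stride=n_steps)
    traj = propagate(potential, snapshot, md)
    out = traj.frame(traj.n_frames - 1).copy(stage="reequilibrated")
    out.meta.update(snapshot.meta)
    return out


def individual_refinement(
    refined_potential: PotentialModel,
    snapshot: Snapshot,
    duration_range_fs: tuple[float, float] = (50.0, 100.0),
    seed: int | None = None,
    dt: float = 0.5,
    fixed_duration_fs: float | None = None,
) -> Snapshot:
    """Short ground-state relaxation under the refined potential.

    The duration is drawn uniformly from ``duration_range_fs`` with the
    per-snapshot seed (pass ``fixed_duration_fs`` to disable randomization —
    useful only to demonstrate the coherent-motion bias the randomization is
    designed to suppress).  The refined potential must share the topology of
    the sampling potential; its parameters may differ.
    """
    lo, hi = duration_range_fs
    if lo >= hi:
        raise ValueError("refinement duration range inverted (min must be < max)")
    if refined_potential.system.n_atoms != snapshot.n_atoms:
        raise ValueError("refined system does not match snapshot atom count")
    rng = np.random.default_rng(seed)
    duration = float(fixed_duration_fs) if fixed_duration_fs is not None else float(rng.uniform(lo, hi))
    n_steps = max(int(round(duration / dt)), 1)
    md = MDConfig(dt=dt, n_steps=n_steps, ensemble="NVE", stride=n_steps)
    traj = propagate(refined_potential, snapshot, md)
    out = traj.frame(traj.n_frames - 1).copy(stage="refined", seed=seed)
    out.meta.update(snapshot.meta)
    out.meta["refinement_duration_fs"] = duration
    return out


def leapfrog_to_verlet(state: LeapfrogState) -> Snapshot:
    """Synchronize a leapfrog state to a common time point tau = t - dt/2.

    Leapfrog restart files store R(t) and v(t - dt/2); velocity-Verlet codes
    expect both at the same time.  The half-step position correction

        R(tau) = R(t) - (dt/2) v(t - dt/2)

    makes the pair synchronous at tau to second order; the velocity is kept
    as v(t - dt/2) unchanged.
    """
    positions = np.asarray(state.positions, dtype=float)
    velocities = np.asarray(state.velocities_half, dtype=float)
    return Snapshot(
        positions=positions - 0.5 * state.dt * velocities,
        velocities=velocities.copy(),
        time_fs=state.time_fs - 0.5 * state.dt,
        stage="production",
        meta={"synchronized_from": "leapfrog"},
    )
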