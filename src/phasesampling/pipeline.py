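"""End-to-end driver: build -> minimize -> MD -> protocols -> spectra.

The pipeline reproduces the full sampling chain on a (toy) system:
minimization, thermalization, equilibration and production MD; snapshot
extraction; then, per snapshot, local temperature adjustment,
re-equilibration and individual refinement; finally excitation tables and
broadened spectra with bootstrap bands for the production and refined
ensembles.  Every stage derives its seed deterministically from the master
seed, and the run directory contains a manifest with a content hash over the
configuration and all ensemble arrays, so a rerun with the same
configuration is verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fileio, spectra
from .forcefield import minimize
from .md import MDConfig, ThermostatConfig, propagate
from .protocols import (
    ProtocolConfig,
    derive_seed,
    extract_snapshots,
    individual_refinement,
    local_temperature_adjustment,
    re_equilibrate,
)
from .system import Snapshot
from .toys import (
    ToyExcitationModel,
    build_toy_potential,
    build_toy_system,
    make_refined_variant,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one sampling run."""

    # system
    n_solvent: int = 30
    droplet_radius: float = 10.5
    temperature: float = 300.0
    # MD stages (fs)
    dt: float = 0.5
    minimize_steps: tuple[int, int] = (400, 800)
    thermalization_fs: float = 1000.0
    equilibration_fs: float = 1000.0
    production_fs: float = 10000.0
    snapshot_stride_fs: float = 500.0
    thermostat_coupling_fs: float = 50.0
    # protocol stages
    do_heating: bool = True
    do_reequilibration: bool = True
    do_refinement: bool = True
    heating_temperature: float = 600.0
    heating_duration_fs: float = 1000.0
    reequilibration_duration_fs: float = 100.0
    refinement_range_fs: tuple[float, float] = (50.0, 100.0)
    refined_bond_shift: float = -0.04
    # spectra
    fwhm: float = 0.15
    n_bootstrap: int = 100
    excitation_noise_sigma: float = 0.05
    grid_start: float = 1.5
    grid_stop: float = 6.5
    grid_step: float = 0.005
    # misc
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        for key in ("minimize_steps", "refinement_range_fs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["minimize_steps"] = list(self.minimize_steps)
        d["refinement_range_fs"] = list(self.refinement_range_fs)
        return d


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    ensembles: dict[str, list[Snapshot]]
    spectra: dict[str, spectra.Spectrum]
    bands: dict[str, spectra.BootstrapBands]

    @property
    def content_hash(self) -> str:
        return self.manifest["content_hash"]


def _digest_snapshots(snaps: list[Snapshot]) -> str:
    h = hashlib.sha256()
    for s in snaps:
        h.update(s.positions.tobytes())
        h.update(s.velocities.tobytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute the full sampling chain and write a reproducible run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dt = config.dt
    seed = config.master_seed

    system, initial = build_toy_system(
        n_solvent=config.n_solvent,
        droplet_radius=config.droplet_radius,
        temperature=config.temperature,
        seed=derive_seed(seed, 0),
    )
    potential = build_toy_potential(system, droplet_radius=config.droplet_radius)

    n_sd, n_cg = config.minimize_steps
    minimized, min_info = minimize(potential, initial.positions, n_sd, n_cg)
    current = initial.copy(positions=minimized)

    thermo = ThermostatConfig(config.temperature, config.thermostat_coupling_fs)

    def nvt(snapshot: Snapshot, duration: float, stage_seed: int, stride: int) -> object:
        steps = max(int(round(duration / dt)), 1)
        cfg = MDConfig(dt=dt, n_steps=steps, ensemble="NVT", seed=stage_seed, stride=stride)
        return propagate(potential, snapshot, cfg, thermo)

    stage_log: dict[str, dict] = {"minimization": {
        "initial_energy_eV": float(min_info["energy_trace"][0]),
        "final_energy_eV": float(min_info["energy_trace"][-1]),
        "grad_norm": min_info["grad_norm"],
    }}

    if config.thermalization_fs > 0:
        traj = nvt(current, config.thermalization_fs, derive_seed(seed, 1),
                   max(int(round(config.thermalization_fs / dt)), 1))
        current = traj.frame(traj.n_frames - 1)
        stage_log["thermalization"] = {"duration_fs": config.thermalization_fs}
    if config.equilibration_fs > 0:
        traj = nvt(current, config.equilibration_fs, derive_seed(seed, 2),
                   max(int(round(config.equilibration_fs / dt)), 1))
        current = traj.frame(traj.n_frames - 1)
        stage_log["equilibration"] = {"duration_fs": config.equilibration_fs}

    stride_steps = max(int(round(config.snapshot_stride_fs / dt)), 1)
    production = nvt(current, config.production_fs, derive_seed(seed, 3), stride_steps)
    snapshots = extract_snapshots(production, config.snapshot_stride_fs)
    stage_log["production"] = {
        "duration_fs": config.production_fs,
        "n_snapshots": len(snapshots),
    }

    protocol = ProtocolConfig(
        snapshot_stride_fs=config.snapshot_stride_fs,
        heating_temperature=config.heating_temperature,
        heating_duration_fs=config.heating_duration_fs,
        reequilibration_duration_fs=config.reequilibration_duration_fs,
        refinement_min_fs=config.refinement_range_fs[0],
        refinement_max_fs=config.refinement_range_fs[1],
        dt=dt,
        master_seed=seed,
    )
    refined_system = make_refined_variant(system, {("bond", (1, 2)): config.refined_bond_shift})
    refined_potential = build_toy_potential(refined_system, droplet_radius=config.droplet_radius)

    ensembles: dict[str, list[Snapshot]] = {"production": snapshots}
    provenance = []
    final_stage = "production"
    finals: list[Snapshot] = []
    for i, snap in enumerate(snapshots):
        chain = ["production"]
        s = snap
        if config.do_heating:
            s = local_temperature_adjustment(potential, s, protocol, seed=derive_seed(seed, 1000 + i))
            chain.append("heated")
        if config.do_reequilibration and config.do_heating:
            s = re_equilibrate(potential, s, config.reequilibration_duration_fs, dt=dt)
            chain.append("reequilibrated")
        if config.do_refinement:
            s = individual_refinement(
                refined_potential, s, config.refinement_range_fs,
                seed=derive_seed(seed, 2000 + i), dt=dt,
            )
            chain.append("refined")
        finals.append(s)
        provenance.append({
            "snapshot": i,
            "chain": chain,
            "heating_seed": derive_seed(seed, 1000 + i) if config.do_heating else None,
            "refinement_seed": derive_seed(seed, 2000 + i) if config.do_refinement else None,
            "refinement_duration_fs": s.meta.get("refinement_duration_fs"),
        })
        final_stage = chain[-1]
    ensembles[final_stage] = finals

    # excitations + spectra for the first and last ensembles
    model = ToyExcitationModel.ring_bond_model(noise_sigma=config.excitation_noise_sigma)
    grid = np.arange(config.grid_start, config.grid_stop + 0.5 * config.grid_step, config.grid_step)
    spectra_out: dict[str, spectra.Spectrum] = {}
    bands_out: dict[str, spectra.BootstrapBands] = {}
    for label, ens in ensembles.items():
        tables = []
        if ens:
            from .toys import generate_excitations

            tables = generate_excitations(model, ens, seed=derive_seed(seed, 5000))
            spectra.write_excitation_tables(out / f"excitations_{label}.tsv", tables)
            spec = spectra.compute_spectrum(tables, fwhm=config.fwhm, grid=grid)
            band = spectra.bootstrap_spectrum(
                tables, fwhm=config.fwhm, grid=grid,
                n_resamples=config.n_bootstrap, seed=derive_seed(seed, 6000),
            )
            spectra_out[label] = spec
            bands_out[label] = band
            spectra.write_spectrum(out / f"spectrum_{label}.tsv", spec, band)

    for label, ens in ensembles.items():
        ens_dir = out / f"ensemble_{label}"
        ens_dir.mkdir(exist_ok=True)
        for i, s in enumerate(ens):
            fileio.write_restart(ens_dir / f"snap_{i:05d}.rst", system.symbols, s)

    digests = {label: _digest_snapshots(ens) for label, ens in ensembles.items()}
    payload = {"config": config.to_dict(), "ensemble_digests": digests}
    content_hash = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config": config.to_dict(),
        "stages": stage_log,
        "provenance": provenance,
        "ensemble_digests": digests,
        "content_hash": content_hash,
        "master_seed": seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(out, manifest, ensembles, spectra_out, bands_out)
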