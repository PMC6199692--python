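"""Shared fixtures: toy systems, minimized geometries, short MD ensembles.

Session-scoped fixtures cache the expensive artifacts (minimization, normal
modes, a short droplet production run) so the suite stays fast.
"""

from __future__ import annotations

import pytest

from phasesampling import forcefield, md, protocols, toys
from phasesampling.forcefield import minimize
from phasesampling.normalmodes import compute_normal_modes


@pytest.fixture(scope="session")
def chromophore():
    """Isolated toy chromophore: (system, initial snapshot)."""
    return toys.build_toy_system(seed=11)


@pytest.fixture(scope="session")
def chromophore_potential(chromophore):
    system, _ = chromophore
    return forcefield.PotentialModel(system)


@pytest.fixture(scope="session")
def minimized_positions(chromophore, chromophore_potential):
    _, snap = chromophore
    positions, info = minimize(chromophore_potential, snap.positions, 400, 1500)
    assert info["grad_norm"] < 1e-4
    return positions


@pytest.fixture(scope="session")
def chromophore_modes(chromophore_potential, minimized_positions):
    return compute_normal_modes(chromophore_potential, minimized_positions,
                                gradient_tolerance=1e-3)


@pytest.fixture(scope="session")
def droplet():
    """Toy chromophore in a 30-particle solvent droplet."""
    system, snap = toys.build_toy_system(seed=12, n_solvent=30, droplet_radius=10.5)
    potential = toys.build_toy_potential(system, droplet_radius=10.5)
    return system, snap, potential


@pytest.fixture(scope="session")
def droplet_production(droplet):
    """Short equilibrated 300 K production run of the droplet system.

    2 ps thermalization followed by 20 ps production recorded every 200 fs;
    returns (system, potential, trajectory, snapshots at 400 fs stride).
    """
    system, snap, potential = droplet
    thermo = md.ThermostatConfig(300.0, 50.0)
    warm = md.propagate(
        potential, snap,
        md.MDConfig(dt=0.5, n_steps=4000, ensemble="NVT", stride=4000, seed=21),
        thermo,
    )
    production = md.propagate(
        potential, warm.frame(warm.n_frames - 1),
        md.MDConfig(dt=0.5, n_steps=40000, ensemble="NVT", stride=400, seed=22),
        thermo,
    )
    snapshots = protocols.extract_snapshots(production, 400.0)
    return system, potential, production, snapshots
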