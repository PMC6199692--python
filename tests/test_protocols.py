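"""Post-processing protocols: extraction, heating, refinement, Eq-of-motion
synchronization."""

import numpy as np
import pytest
from scipy import stats

from phasesampling import toys, units
from phasesampling.forcefield import PotentialModel
from phasesampling.md import MDConfig, Trajectory, instantaneous_temperature, propagate
from phasesampling.protocols import (
    LeapfrogState,
    ProtocolConfig,
    derive_seed,
    extract_snapshots,
    individual_refinement,
    leapfrog_to_verlet,
    local_temperature_adjustment,
    re_equilibrate,
)
from phasesampling.system import BondTerm, InternalCoordinate, MolecularSystem, Snapshot, evaluate_internal


def fake_trajectory(n_frames: int, interval_fs: float, n_atoms: int = 2) -> Trajectory:
    """Bookkeeping-only trajectory with distinguishable frames."""
    times = np.arange(n_frames) * interval_fs
    pos = np.zeros((n_frames, n_atoms, 3))
    pos[:, 0, 0] = np.arange(n_frames)  # make frames distinguishable
    vel = np.ones((n_frames, n_atoms, 3)) * 1e-3
    return Trajectory(times, pos, vel, np.zeros(n_frames), np.zeros(n_frames))


class TestExtractSnapshots:
    def test_ten_nanoseconds_at_20ps_stride_gives_500(self):
        """The canonical production bookkeeping: 10 ns / 20 ps = 500 samples."""
        traj = fake_trajectory(501, 20_000.0)  # frames every 20 ps, 10 ns total
        snaps = extract_snapshots(traj, 20_000.0)
        assert len(snaps) == 500

    def test_one_nanosecond_at_100ps_stride_times(self):
        traj = fake_trajectory(101, 10_000.0)  # 1 ns recorded every 10 ps
        snaps = extract_snapshots(traj, 100_000.0)
        assert len(snaps) == 10
        assert [s.time_fs for s in snaps] == [
            pytest.approx(k * 100_000.0) for k in range(1, 11)
        ]

    def test_too_short_trajectory_warns_and_returns_empty(self):
        traj = fake_trajectory(3, 50.0)  # 100 fs total
        with pytest.warns(UserWarning, match="shorter"):
            snaps = extract_snapshots(traj, 20_000.0)
        assert snaps == []

    def test_sub_frame_stride_rejected(self):
        traj = fake_trajectory(10, 100.0)
        with pytest.raises(ValueError, match="smaller"):
            extract_snapshots(traj, 50.0)

    def test_non_multiple_stride_rejected(self):
        traj = fake_trajectory(10, 100.0)
        with pytest.raises(ValueError, match="multiple"):
            extract_snapshots(traj, 250.0)

    def test_snapshots_carry_velocities(self):
        traj = fake_trajectory(11, 100.0)
        snaps = extract_snapshots(traj, 200.0)
        assert len(snaps) == 5
        assert np.all(snaps[0].velocities == 1e-3)


class TestLocalTemperatureAdjustment:
    def test_environment_frozen_and_velocities_reset(self, droplet_production):
        system, potential, _, snapshots = droplet_production
        snap = snapshots[0]
        config = ProtocolConfig(heating_temperature=600.0, heating_duration_fs=1000.0)
        heated = local_temperature_adjustment(potential, snap, config, seed=3)
        env = system.environment
        assert heated.stage == "heated"
        np.testing.assert_array_equal(heated.positions[env], snap.positions[env])
        np.testing.assert_array_equal(heated.velocities[env], snap.velocities[env])
        # the solute, meanwhile, did move
        assert np.abs(heated.positions[system.solute] - snap.positions[system.solute]).max() > 1e-3

    def test_solute_reaches_target_temperature(self, droplet_production):
        """300 K production snapshots heated to 600 K within 10% (ensemble mean)."""
        system, potential, _, snapshots = droplet_production
        config = ProtocolConfig(heating_temperature=600.0, heating_duration_fs=1500.0)
        temps = []
        for i, snap in enumerate(snapshots[:6]):
            heated = local_temperature_adjustment(potential, snap, config,
                                                  seed=derive_seed(40, i))
            temps.append(heated.meta["heated_solute_temperature_K"])
        assert np.mean(temps) == pytest.approx(600.0, rel=0.10)

    def test_null_protocol_at_production_temperature(self, droplet_production):
        """Heating at the production temperature leaves the solute kinetic
        temperature statistically unchanged (one-sample t test, alpha=0.01)."""
        system, potential, _, snapshots = droplet_production
        config = ProtocolConfig(heating_temperature=300.0, heating_duration_fs=1000.0)
        temps = [
            local_temperature_adjustment(potential, s, config, seed=derive_seed(41, i))
            .meta["heated_solute_temperature_K"]
            for i, s in enumerate(snapshots[:8])
        ]
        t_stat, p = stats.ttest_1samp(temps, 300.0)
        assert p > 0.01

    def test_degenerate_without_environment_warns(self, chromophore, chromophore_potential):
        _, snap = chromophore
        config = ProtocolConfig(heating_duration_fs=50.0)
        with pytest.warns(UserWarning, match="environment"):
            local_temperature_adjustment(chromophore_potential, snap, config, seed=1)


class TestReEquilibrate:
    def test_zero_duration_is_identity(self, droplet_production):
        _, potential, _, snapshots = droplet_production
        out = re_equilibrate(potential, snapshots[0], 0.0)
        np.testing.assert_array_equal(out.positions, snapshots[0].positions)
        assert out.stage == "reequilibrated"

    def test_brief_window_bounds_energy_leak(self, droplet_production):
        """Over 100 fs the hot solute loses < 15% of its kinetic temperature."""
        system, potential, _, snapshots = droplet_production
        config = ProtocolConfig(heating_temperature=600.0, heating_duration_fs=1500.0)
        drops = []
        for i, snap in enumerate(snapshots[:5]):
            heated = local_temperature_adjustment(potential, snap, config,
                                                  seed=derive_seed(42, i))
            hot = heated.meta["heated_solute_temperature_K"]
            out = re_equilibrate(potential, heated, 100.0)
            after = instantaneous_temperature(out, system.masses, selection=system.solute)
            drops.append(after / hot)
        # instantaneous temperatures fluctuate strongly for 8 atoms; the
        # ensemble-averaged retention is what the brief window must protect
        assert np.mean(drops) > 0.85


class TestIndividualRefinement:
    def test_noop_refinement_preserves_distributions(self, droplet_production):
        """Refining under the *same* potential leaves internal coordinates
        statistically unchanged (KS test, alpha=0.01)."""
        system, potential, _, snapshots = droplet_production
        bond = InternalCoordinate("distance", toys.RING_BOND)
        before = np.array([evaluate_internal(bond, s) for s in snapshots])
        refined = [
            individual_refinement(potential, s, (50.0, 100.0), seed=derive_seed(50, i))
            for i, s in enumerate(snapshots)
        ]
        after = np.array([evaluate_internal(bond, s) for s in refined])
        _, p = stats.ks_2samp(before, after)
        assert p > 0.01
        assert all(s.stage == "refined" for s in refined)
        assert all(50.0 <= s.meta["refinement_duration_fs"] <= 100.0 for s in refined)

    def test_shifted_bond_relaxes_to_refined_equilibrium(self, droplet_production):
        """A -0.04 A equilibrium shift pulls the ensemble mean onto the
        refined value within one standard error after 50-100 fs."""
        system, potential, _, snapshots = droplet_production
        refined_system = toys.make_refined_variant(system)
        refined_potential = toys.build_toy_potential(refined_system, droplet_radius=10.5)
        bond = InternalCoordinate("distance", toys.RING_BOND)
        refined = [
            individual_refinement(refined_potential, s, (50.0, 100.0),
                                  seed=derive_seed(51, i))
            for i, s in enumerate(snapshots)
        ]
        after = np.array([evaluate_internal(bond, s) for s in refined])
        r0_refined = next(b.r0 for b in refined_system.bonds
                          if (b.i, b.j) == toys.RING_BOND)
        sem = after.std(ddof=1) / np.sqrt(after.size)
        assert abs(after.mean() - r0_refined) < sem + 1e-12

    def test_fixed_duration_exhibits_coherent_bias(self, droplet_production):
        """Identical durations leave a coherent oscillation in the ensemble
        mean; randomized durations damp it (the point of the randomization)."""
        system, potential, _, snapshots = droplet_production
        refined_system = toys.make_refined_variant(system)
        refined_potential = toys.build_toy_potential(refined_system, droplet_radius=10.5)
        bond = InternalCoordinate("distance", toys.RING_BOND)
        subset = snapshots[:25]

        fixed_means = []
        for duration in (55.0, 60.0, 65.0, 70.0, 75.0):
            vals = [
                evaluate_internal(bond, individual_refinement(
                    refined_potential, s, (50.0, 100.0), seed=0,
                    fixed_duration_fs=duration))
                for s in subset
            ]
            fixed_means.append(np.mean(vals))
        random_means = []
        for rep in range(5):
            vals = [
                evaluate_internal(bond, individual_refinement(
                    refined_potential, s, (50.0, 100.0),
                    seed=derive_seed(60 + rep, i)))
                for i, s in enumerate(subset)
            ]
            random_means.append(np.mean(vals))
        assert np.std(fixed_means) > 2.0 * np.std(random_means)

    def test_inverted_duration_range_rejected(self, droplet_production):
        _, potential, _, snapshots = droplet_production
        with pytest.raises(ValueError, match="inverted"):
            individual_refinement(potential, snapshots[0], (100.0, 50.0), seed=1)

    def test_refinement_preserves_metadata_chain(self, droplet_production):
        _, potential, _, snapshots = droplet_production
        snap = snapshots[0]
        snap.meta["snapshot_index"] = 7
        out = individual_refinement(potential, snap, (50.0, 100.0), seed=1)
        assert out.meta["snapshot_index"] == 7
        assert out.n_atoms == snap.n_atoms


class TestLeapfrogConversion:
    def test_zero_velocity_leaves_positions_unchanged(self):
        state = LeapfrogState(positions=np.ones((3, 3)),
                              velocities_half=np.zeros((3, 3)), dt=0.5)
        out = leapfrog_to_verlet(state)
        np.testing.assert_array_equal(out.positions, np.ones((3, 3)))

    def test_half_step_position_correction_value(self):
        """R(tau) = R(t) - (dt/2) v: 1.0 - 0.25*0.01 = 0.9975 A."""
        state = LeapfrogState(positions=np.array([[1.0, 0, 0]]),
                              velocities_half=np.array([[0.01, 0, 0]]), dt=0.5)
        out = leapfrog_to_verlet(state)
        assert out.positions[0, 0] == pytest.approx(0.9975, abs=1e-12)
        np.testing.assert_array_equal(out.velocities, state.velocities_half)

    @staticmethod
    def _phase_space_errors(dt):
        """Leapfrog-propagate a harmonic diatomic, then measure the
        phase-space mismatch against the analytic orbit before and after the
        half-step synchronization."""
        k, mass, r0, stretch = 0.05, 20.0, 1.5, 0.2
        system = MolecularSystem(symbols=["C", "C"], masses=np.full(2, mass),
                                 charges=np.zeros(2), bonds=[BondTerm(0, 1, k, r0)])
        pot = PotentialModel(system)
        snap = Snapshot(positions=np.array([[0.0, 0, 0], [r0 + stretch, 0, 0]]),
                        velocities=np.zeros((2, 3)))
        n_steps = int(round(200.0 / dt))
        traj = propagate(pot, snap, MDConfig(dt=dt, n_steps=n_steps,
                                             integrator="leapfrog", stride=n_steps))
        mu = mass / 2
        omega = np.sqrt(2 * k * units.EV_TO_AMU_A2_FS2 / mu)

        def analytic(t):
            return (r0 + stretch * np.cos(omega * t),
                    -stretch * omega * np.sin(omega * t))

        r_t = traj.positions[-1, 1, 0] - traj.positions[-1, 0, 0]
        v_half = traj.velocities[-1, 1, 0] - traj.velocities[-1, 0, 0]
        t_end = traj.times[-1]

        def mismatch(r, v, t):
            ra, va = analytic(t)
            return np.hypot(r - ra, (v - va) / omega)

        before = mismatch(r_t, v_half, t_end)  # naive: treat the pair as synchronous
        state = LeapfrogState(positions=traj.positions[-1],
                              velocities_half=traj.velocities[-1], dt=dt)
        conv = leapfrog_to_verlet(state)
        r_tau = conv.positions[1, 0] - conv.positions[0, 0]
        after = mismatch(r_tau, v_half, t_end - dt / 2)
        return before, after

    def test_synchronization_improves_order_of_accuracy(self):
        """Mismatch shrinks ~O(dt) before conversion and ~O(dt^2) after."""
        dts = [0.5, 0.25, 0.125]
        before, after = zip(*(self._phase_space_errors(dt) for dt in dts))
        order_before = np.polyfit(np.log(dts), np.log(before), 1)[0]
        order_after = np.polyfit(np.log(dts), np.log(after), 1)[0]
        assert order_before == pytest.approx(1.0, abs=0.35)
        assert order_after >= 1.7
        assert all(a < b for a, b in zip(after, before))


class TestSeeding:
    def test_derived_seeds_are_deterministic_and_bounded(self):
        s1 = derive_seed(1234, 7)
        s2 = derive_seed(1234, 7)
        s3 = derive_seed(1234, 8)
        assert s1 == s2 != s3
        assert 0 <= s1 < 2**31
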