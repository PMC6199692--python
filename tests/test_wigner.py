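"""Wigner sampling: level selection, phase-space moments, shearing artifact."""

import numpy as np
import pytest

from phasesampling import toys, units, wigner
from phasesampling.normalmodes import NormalModeSet
from phasesampling.system import evaluate_internal, kinetic_energy_per_atom


def single_mode_set(wavenumber):
    masses = np.array([6.0, 6.0])
    mode = np.zeros((1, 2, 3))
    mode[0, 0, 0] = np.sqrt(0.5)
    mode[0, 1, 0] = -np.sqrt(0.5)
    return NormalModeSet(reference=np.array([[0.0, 0, 0], [1.5, 0, 0]]),
                         masses=masses, wavenumbers=np.array([float(wavenumber)]),
                         modes=mode, symbols=["C", "C"])


def normal_coordinates(snapshots, modes, mode_index=0):
    sq = np.sqrt(modes.masses)[:, None]
    return np.array([
        np.sum((s.positions - modes.reference) * sq * modes.modes[mode_index])
        for s in snapshots
    ])


class TestBoltzmannLevels:
    def test_zero_temperature_always_ground_state(self):
        levels = wigner.boltzmann_select_level(417.0, 0.0, rng=1, size=1000)
        assert np.all(levels == 0)

    def test_stiff_mode_at_room_temperature_stays_in_ground_state(self):
        """3000 cm^-1 at 300 K: P(0) > 0.999."""
        levels = wigner.boltzmann_select_level(3000.0, 300.0, rng=2, size=10_000)
        assert np.mean(levels == 0) > 0.999

    def test_417cm_mode_has_two_quantum_boltzmann_factor(self):
        """h c 417 cm^-1 = 2 k_B 300 K exactly, so P(0) = 1 - e^-2 = 0.865."""
        levels = wigner.boltzmann_select_level(417.0, 300.0, rng=3, size=10_000)
        assert np.mean(levels == 0) == pytest.approx(1 - np.exp(-2.0), abs=0.01)

    def test_distribution_matches_geometric_closed_form(self):
        levels = wigner.boltzmann_select_level(417.0, 300.0, rng=4, size=20_000)
        for n in range(4):
            expected = wigner.boltzmann_level_probability(417.0, 300.0, n)
            assert np.mean(levels == n) == pytest.approx(expected, abs=0.01)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            wigner.boltzmann_select_level(-10.0, 300.0)
        with pytest.raises(ValueError):
            wigner.boltzmann_select_level(417.0, -1.0)


class TestSampleWigner:
    def test_all_modes_excluded_returns_reference_at_rest(self):
        modes = single_mode_set(417.0)
        spec = wigner.WignerSpec(temperature=300.0, excluded_modes=frozenset({0}), seed=1)
        snaps = wigner.sample_wigner(modes, spec, 10)
        for s in snaps:
            np.testing.assert_array_equal(s.positions, modes.reference)
            np.testing.assert_array_equal(s.velocities, 0.0)
            assert s.stage == "wigner"

    def test_ground_state_variance_and_kinetic_energy(self):
        """Var(Q) = hbar/(2 omega) and <E_kin> = hbar omega / 4 at T = 0."""
        modes = single_mode_set(417.0)
        omega = units.omega_from_wavenumber(417.0)
        snaps = wigner.sample_wigner(modes, wigner.WignerSpec(temperature=0.0, seed=5),
                                     50_000)
        q = normal_coordinates(snaps, modes)
        assert q.var() == pytest.approx(units.HBAR_AMU_A2_FS / (2 * omega), rel=0.02)
        ekin = np.array([kinetic_energy_per_atom(s, modes.masses).sum() for s in snaps])
        assert ekin.mean() == pytest.approx(0.25 * units.HBAR_EV_FS * omega, rel=0.02)

    def test_classical_limit_mode_obeys_thermal_coth_law(self):
        """A 7 cm^-1 mode at 300 K: Var(Q) = (hbar/2w) coth(hbar w / 2 kT)."""
        modes = single_mode_set(7.0)
        omega = units.omega_from_wavenumber(7.0)
        spec = wigner.WignerSpec(temperature=300.0, max_level=2000, seed=6)
        snaps = wigner.sample_wigner(modes, spec, 20_000)
        q = normal_coordinates(snaps, modes)
        beta_q = units.HBAR_EV_FS * omega / (units.KB * 300.0)
        target = units.HBAR_AMU_A2_FS / (2 * omega) / np.tanh(beta_q / 2)
        assert q.var() == pytest.approx(target, rel=0.05)

    def test_ensemble_means_vanish(self):
        modes = single_mode_set(417.0)
        snaps = wigner.sample_wigner(modes, wigner.WignerSpec(temperature=300.0, seed=7),
                                     20_000)
        q = normal_coordinates(snaps, modes)
        v = np.array([s.velocities[0, 0] for s in snaps])
        assert abs(q.mean()) < 3 * q.std() / np.sqrt(q.size)
        assert abs(v.mean()) < 3 * v.std() / np.sqrt(v.size)

    def test_imaginary_mode_rejected_with_indices(self):
        modes = single_mode_set(-50.0)
        with pytest.raises(ValueError, match=r"\[0\]"):
            wigner.sample_wigner(modes, wigner.WignerSpec(seed=1), 5)


class TestConformerUnion:
    def test_explicit_counts_reproduce_abundance_fractions(self, chromophore_modes):
        """Counts 200/1000/100 give 15%/77%/8% of a 1300-geometry union."""
        confs = [
            wigner.ConformerSpec(chromophore_modes, count=200, label="A"),
            wigner.ConformerSpec(chromophore_modes, count=1000, label="B"),
            wigner.ConformerSpec(chromophore_modes, count=100, label="A'"),
        ]
        spec = wigner.WignerSpec(temperature=300.0, seed=8,
                                 excluded_modes=frozenset({0}))
        snaps = wigner.sample_conformer_union(confs, spec)
        assert len(snaps) == 1300
        labels = [s.meta["conformer"] for s in snaps]
        assert labels.count("A") / 1300 == pytest.approx(0.1538, abs=1e-3)
        assert labels.count("B") / 1300 == pytest.approx(0.7692, abs=1e-3)
        assert labels.count("A'") / 1300 == pytest.approx(0.0769, abs=1e-3)

    def test_single_conformer_gets_everything(self, chromophore_modes):
        confs = [wigner.ConformerSpec(chromophore_modes, weight=1.0, label="only")]
        spec = wigner.WignerSpec(temperature=300.0, seed=9, excluded_modes=frozenset({0}))
        snaps = wigner.sample_conformer_union(confs, spec, total=25)
        assert len(snaps) == 25
        assert all(s.meta["conformer"] == "only" for s in snaps)

    def test_boltzmann_energy_weights_give_three_to_one(self, chromophore_modes):
        """Delta E = kT ln 3 yields counts in a 3:1 ratio."""
        kT = units.KB * 300.0
        confs = [
            wigner.ConformerSpec(chromophore_modes, energy=0.0, label="lo"),
            wigner.ConformerSpec(chromophore_modes, energy=kT * np.log(3.0), label="hi"),
        ]
        spec = wigner.WignerSpec(temperature=300.0, seed=10, excluded_modes=frozenset({0}))
        snaps = wigner.sample_conformer_union(confs, spec, total=400)
        labels = [s.meta["conformer"] for s in snaps]
        assert labels.count("lo") == 300
        assert labels.count("hi") == 100

    def test_zero_weights_rejected(self, chromophore_modes):
        confs = [wigner.ConformerSpec(chromophore_modes, weight=0.0)]
        with pytest.raises(ValueError):
            wigner.sample_conformer_union(confs, wigner.WignerSpec(seed=1), total=10)


class TestShearingArtifact:
    def test_zero_displacement_returns_equilibrium(self, chromophore):
        system, snap = chromophore
        modes = toys.rigid_rotor_modes(system, snap.positions)
        prof = wigner.shear_width_profile(modes, 0, toys.torsion_coordinate(),
                                          toys.MARKER_PAIR, np.array([0.0]))
        assert prof[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert prof[0, 1] == pytest.approx(4.2, abs=1e-9)

    def test_linear_displacement_follows_inverse_cosine_law(self, chromophore):
        """Shearing: width(theta) = w_eq / cos(theta - theta_eq); at 60 deg
        off equilibrium the rotor appears stretched by exactly 2x."""
        system, snap = chromophore
        modes = toys.rigid_rotor_modes(system, snap.positions)
        grid = np.linspace(-5.2, 5.2, 81)
        prof = wigner.shear_width_profile(modes, 0, toys.torsion_coordinate(),
                                          toys.MARKER_PAIR, grid)
        theta = np.radians(prof[:, 0])
        predicted = 4.2 / np.cos(theta)
        np.testing.assert_allclose(prof[:, 1], predicted, rtol=5e-3)
        # interpolate the width at 60 degrees: factor 2.0 within 0.5%
        w60 = np.interp(60.0, prof[:, 0], prof[:, 1])
        assert w60 / 4.2 == pytest.approx(2.0, rel=5e-3)

    def test_true_rotation_keeps_width_constant(self, chromophore):
        system, snap = chromophore
        prof = wigner.rigid_rotation_profile(
            snap.positions, (0, 5), toys.ROTOR_ATOMS, toys.torsion_coordinate(),
            toys.MARKER_PAIR, np.linspace(-90, 90, 37),
        )
        np.testing.assert_allclose(prof[:, 1], 4.2, rtol=1e-9)
        assert prof[:, 0].min() < -85 and prof[:, 0].max() > 85

    def test_mode_index_out_of_range(self, chromophore):
        system, snap = chromophore
        modes = toys.rigid_rotor_modes(system, snap.positions)
        with pytest.raises(IndexError):
            wigner.shear_width_profile(modes, 3, toys.torsion_coordinate(),
                                       toys.MARKER_PAIR, np.array([0.0]))


@pytest.fixture(scope="module")
def ensembles(chromophore_modes):
    spec_with = wigner.WignerSpec(temperature=300.0, max_level=200, seed=11)
    spec_without = wigner.WignerSpec(temperature=300.0, max_level=200, seed=11,
                                     excluded_modes=frozenset({0}))
    with_t = wigner.sample_wigner(chromophore_modes, spec_with, 600)
    without_t = wigner.sample_wigner(chromophore_modes, spec_without, 600)
    return with_t, without_t


class TestTorsionInclusionContrast:
    """The narrow-vs-wide torsion distribution and the width correlation."""

    def test_excluding_torsion_collapses_angle_spread(self, ensembles):
        with_t, without_t = ensembles
        tor = toys.torsion_coordinate()
        s_with = np.std([evaluate_internal(tor, s) for s in with_t])
        s_without = np.std([evaluate_internal(tor, s) for s in without_t])
        assert s_with / s_without > 3.0

    def test_torsion_inclusion_couples_angle_to_marker_width(self, ensembles):
        """|theta - theta_eq| correlates with the marker width only when the
        torsion mode is sampled linearly (the shearing artifact)."""
        from phasesampling.analysis import correlation_scan

        with_t, without_t = ensembles
        tor = toys.torsion_coordinate()

        def arrays(snaps):
            theta = np.array([evaluate_internal(tor, s) for s in snaps])
            width = np.array([
                np.linalg.norm(s.positions[6] - s.positions[7]) for s in snaps
            ])
            return np.abs(theta - np.median(theta)), width

        x, y = arrays(with_t)
        res = correlation_scan(x, y, seed=1)
        assert res.r > 0.5
        assert res.significant
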