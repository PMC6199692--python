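# Methods

`phasesampling` generates ensembles of initial conditions — synchronized
geometries and velocities — for simulating absorption spectra and
nonadiabatic excited-state dynamics of a chromophore embedded in an
environment.  It implements the two standard sampling routes (Wigner
"quantum" sampling of harmonic vibrational states, and classical MD
sampling), the diagnostics that expose their failure modes, and two
post-processing protocols that correct the main deficiencies of MD
sampling: *local temperature adjustment* (missing zero-point energy) and
*individual refinement* (force-field bias in fast coordinates).  Everything
runs on self-contained toy systems, so the full chain is testable without
external electronic-structure engines.

## Units and constants

Internal units are Å, fs, amu, eV, K, elementary charge.  One useful
identity anchors the energy bookkeeping: k_B·300 K = 25.85 meV equals the
zero-point energy ½hcν̃ of a mode at 417 cm⁻¹.  A classical trajectory at
300 K gives *every* mode ≈26 meV, whereas quantum mechanics demands at least
½ħω per mode — the mismatch that motivates local temperature adjustment.

## The toy chromophore

An 8-atom model with a heavy central atom M (100 amu), a rigid planar
4-atom ring ligand, and a 3-atom rotor ligand (anchor N plus two marker
atoms 4.2 Å apart whose distance is the rotor "width").  The skeleton is
bent (ring attached 120° from the rotor axis) so that every out-of-plane
motion is restrained at first order through improper dihedrals; with a
collinear skeleton, tilt modes are restrained only quartically and collapse
to spurious few-cm⁻¹ frequencies.

The rotor turns about the M–N axis under a five-term cosine potential
(coefficients 0.084/0.006/0.028/0.018 eV for periodicities 1–4 plus an
0.018 eV asymmetry term), tuned once so that:

* there are exactly three minima per period, at −90°, ≈−1.5° and +90°
  (labelled A, B, A′), the central one deepest;
* well separations and barriers are of order 1 kcal/mol (profile maximum
  ≈0.11 eV near 180°), so the rotor is almost free at room temperature;
* the analytic Boltzmann occupancies of the three wells at 300 K are
  ≈14.5 / 77.5 / 8.0 % — the composition used for conformer-union
  bookkeeping;
* the lowest normal mode of the isolated molecule is this torsion
  (≈103 cm⁻¹, next mode 1.7× higher).  Scaling the torsion coefficients
  down (`torsion_scale`) with the nonbonded terms off (`nonbonded_scale=0`)
  tunes the mode into the single-digit-cm⁻¹ regime of a nearly free rotor;
  with nonbonded terms on, their curvature along the torsion dominates once
  the barrier is small.

Bonds and angles are harmonic (V = k(r−r₀)², k(θ−θ₀)²; note the
k-convention without the ½).  Nonbonded interactions are 12-6
Lennard-Jones plus Coulomb with a C¹ polynomial switch over the last 1 Å
before a 10 Å cutoff, which keeps NVE energy conservation clean.  The
solvent is a droplet of single-site LJ particles (18 amu, ε=6.5 meV,
σ=3.15 Å, no charge) confined by a harmonic spherical wall — protocol
logic, not water physics, is what the environment must provide.  Periodic
boundary conditions, barostats and Ewald sums are deliberately out of
scope; the production stage runs NVT in the droplet.

A *refined* force-field variant (same topology, shifted equilibrium
values; default: one ring bond −0.04 Å) stands in for the higher-level
QM/MM potential that the individual-refinement protocol would use in a real
application.  The operation contract is engine-agnostic: any second
potential sharing the topology works.

## MD engine

Velocity Verlet and leapfrog integrators at Δt = 0.5 fs by default (short
enough that X–H-like stretches need no constraint algorithm).  Leapfrog
frames pair R(t) with v(t−Δt/2), the convention of leapfrog restart files;
the synchronization operation R(τ) = R(t) − (Δt/2)·v(t−Δt/2) converts such
a pair for velocity-Verlet use.  On an analytic harmonic orbit the naive
pairing errs at O(Δt) and the synchronized pair at O(Δt²), which the tests
verify over Δt ∈ {0.5, 0.25, 0.125} fs.

Frozen atoms are excluded from integration, thermostatting and DOF counts,
but their interactions still act on mobile atoms (the frozen solvent cage
confines the solute during heating).

Thermostats:

* **CSVR** (stochastic velocity rescaling) — canonical for the total
  kinetic energy; the default for production sampling.
* **Langevin** — per-DOF Ornstein–Uhlenbeck friction and noise with
  γ = 1/coupling-time.  This is the default for the local-heating stage,
  for a measured reason: a global rescaling factor cannot move energy
  *between* modes, and the toy chromophore is quasi-harmonic, so in a 20 ps
  600 K CSVR run the per-mode kinetic temperatures stayed spread over
  250–1800 K while the total read 600 K.  Langevin thermalizes each mode
  directly, which is what "reheat the chromophore to 600 K" has to mean
  for the per-atom kinetic-energy distributions to come out right.
* **Berendsen** — weak-coupling rescaling, not canonical; rough
  thermalization only.

Stability guard: any per-step displacement above 1 Å aborts with the step
index.

## Normal modes and Wigner sampling

Hessians are built from central differences of the analytic forces
(step 0.005 Å), mass-weighted, with Eckart translation/rotation vectors
projected out before diagonalization.  Imaginary frequencies are carried as
negative wavenumbers and flagged, never dropped.  Molden frequency files
([FR-COORD]/[FREQ]/[FR-NORM-COORD], bohr) can be written and read back;
read modes are re-mass-weighted and re-orthonormalized.

Finite-temperature Wigner sampling draws, per mode, a vibrational level n
from the Boltzmann distribution P(n) = (1−q)qⁿ with q = exp(−hcν̃/k_BT)
(inverse-CDF on the truncated geometric distribution, exactly reproducible
from the seed), then a phase-space point from that level's Wigner function.
Levels are selected independently per mode.  Numerical strategy per level:

* n = 0: the Wigner function is Gaussian — sampled directly (exact).
* 1 ≤ n ≤ 8: rejection sampling restricted to the positive region of the
  (partly negative) Laguerre-form Wigner function, normalized over it.
* n > 8: the semiclassical ring r² = 2n+1 in dimensionless phase space,
  with uniform phase.

The threshold is deliberately low.  Restricting to the positive region
biases the per-level variance low (exactly 5/6 of ħ(n+½)/ω at n = 1), and
in classical-limit modes — where dozens of levels are populated — that bias
accumulates and would break the thermal variance law
Var(Q) = (ħ/2ω)·coth(ħω/2k_BT).  The ring carries the exact second moments
of every level and is the large-n limit of the Wigner function, so with the
switch at n = 8 the sampled thermal variance of a 7 cm⁻¹ mode at 300 K is
correct to better than 1%, while the low levels keep the conventional
positive-region treatment.  Residual effect: for modes where n = 1–8
dominates thermally (a few hundred cm⁻¹ at 300 K) the thermal variance runs
≈5% low; the ground state is exact.

Multi-minimum systems are sampled as a union of per-conformer Wigner
ensembles with counts given explicitly or derived from Boltzmann factors of
the minimum energies (largest-remainder rounding; no per-conformer ZPE
correction).

### The shearing artifact

A torsion represented as a *linear* normal-mode vector displaces atoms on
straight lines tangent to their rotation circles, so a finite displacement
*shears* the rotating group instead of rotating it: the marker-pair width
grows as w_eq/cos(Θ−Θ_eq) — exactly 2× at 60° off equilibrium.  The
package exposes this as `shear_width_profile` (linear displacement) against
`rigid_rotation_profile` (true rotation; width constant), and the Wigner
ensembles reproduce the statistical signature: with the torsion mode
included, |Θ−Θ_eq| correlates positively with the width and the Θ spread is
>3× wider than with the mode excluded, while MD ensembles rotate truly and
show no such correlation.

## Sampling protocols

Stage order is fixed: production snapshot → local heating (environment
frozen) → environment-velocity reset → re-equilibration (all mobile) →
individual refinement.

**Local temperature adjustment.**  For each production snapshot the
environment is frozen and the solute is thermostatted (Langevin) at the
temperature whose classical energy matches the vibrational budget —
E/(n_dof·k_B); ≈600 K when H-stretch-like modes are discounted from the
ZPE sum, ≈800 K for the full sum.  After heating, environment velocities
are reset to the production values, and a brief (100 fs) all-mobile NVE
window lets the solvent shells adapt.  NVE, not NVT: a thermostat here
would drain exactly the energy the protocol injected.  Environment
positions pass through bit-identically.

**Individual refinement.**  Each snapshot is propagated for a duration
drawn uniformly from 50–100 fs under the refined potential (NVE,
ground state).  The switch of potentials launches a *coherent* oscillation
of the shifted coordinate across the whole ensemble; randomizing the
duration dephases it (the tests show the fixed-duration ensemble mean
oscillating with the duration while the randomized mean sits on the refined
equilibrium within one standard error).  Durations use per-snapshot seeds
derived as `SeedSequence(master, spawn_key=(index,))` — reproducible under
parallel execution; the same rule seeds every per-snapshot stage, so one
master seed makes the whole pipeline bit-deterministic.

## Ensemble analysis

Internal-coordinate histograms (Scott's-rule bins, Poisson-weighted
centers) are fit with least-squares Gaussians; a relative RMS residual
above 0.15 of the peak flags a non-Gaussian distribution.  Per-atom
effective temperatures fit the Maxwell–Boltzmann kinetic-energy density
f(E) = 2√(E/π)(k_BT)^(−3/2)·e^(−E/k_BT) to kinetic-energy histograms
(zero-count bins dropped — flooring them biases T low), with the moment
identity T = (2/3)⟨E⟩/k_B as closed-form cross-check; both recover T within
10% at 500 samples.  Conformers classify by torsion bands: B for
|Θ| < 45°, A for [−135°, −45°], A′ for [45°, 135°], wraparound to the
nearer of A/A′.  Correlation scans report Pearson r with a percentile
bootstrap CI.

## Spectra

σ(E) = Σ_g Σ_i f_gi·exp(−4 ln 2 (E−E_gi)²/FWHM²) — the literal peak-height
convention, unnormalized (a 1/n option exists for cross-ensemble
comparison).  Defaults: FWHM 0.15 eV, grid 1.5–6.5 eV at 5 meV.  The
density of states is the same sum with all strengths set to 1.  Bootstrap
bands resample n geometries with replacement (index matrix drawn up front
from one seed), recompute the spectrum, and report the per-grid-point mean
and standard deviation; mean ± 3σ covers the full-ensemble spectrum at
≥99% of grid points when the resample distribution is approximately normal,
and the band width scales as 1/√n.  The wavelength axis is derived as hc/E
at write time; energy is primary.

The toy excitation model is linear-plus-noise: E_gi = E₀ᵢ + Σ c·(x−x_ref) +
ε.  With the default coupling of −5 eV/Å between the lowest state and the
ring bond, the −0.04 Å refined-bond shift predicts a +0.2 eV blue shift of
the low-energy band — measured in the end-to-end test as the
intensity-weighted band centroid (which tracks the mean excitation energy
exactly under the symmetric kernel; an argmax peak estimate is grid- and
noise-limited at small ensemble sizes).

## Problem sizes

The shipped defaults run at desk scale, chosen so each stage still has the
statistics its contract needs: droplet of ~30 solvent particles,
2 ps thermalization + 20 ps production sampled every 400 fs (~50
snapshots), 1.5 ps heating windows, 50–100 fs refinements, 100–1000
bootstrap resamples, 2·10⁴–5·10⁴ Wigner draws.  The conformer-occupancy
check uses a 160 ps single-molecule NVT run (~80 barrier crossings).

## What the toy fixtures do and do not show

Passing tests demonstrate the *protocol logic*: bookkeeping, determinism,
conservation laws, the statistical contracts of each stage, and the
direction and magnitude of the spectral effects under a known linear
excitation model.  They do not demonstrate chemical realism: the solvent
has no hydrogen-bond structure, the torsion profile is hand-tuned rather
than derived, electronic-structure quantities are modelled, and NPT
production is replaced by NVT droplets (assumed negligible for protocol
validation at this scale, not asserted).  Quantitative reproduction of any
real chromophore's spectra requires real force fields and excited-state
calculations upstream of this package.

## Known limitations

* Positive-region Wigner sampling of levels 1–8 under-disperses those
  levels by up to ~17% in variance (see above); only modes whose thermal
  population concentrates there are affected.
* The Maxwell–Boltzmann histogram fit needs ≳100 samples; below that the
  closed-form estimator is the only reliable route.
* Langevin thermostatting does not conserve momentum; the droplet wall
  makes this immaterial here.
* The minimizer (steepest descent + Polak–Ribière conjugate gradient with
  backtracking) targets toy-scale robustness, not large-system
  performance.
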