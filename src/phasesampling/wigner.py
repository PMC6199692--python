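"""Wigner-distribution sampling of harmonic vibrational states.

For each included normal mode a vibrational level ``n`` is drawn from the
Boltzmann distribution at the sampling temperature,

    P(n) = (1 - q) q^n,   q = exp(-h c nu / k_B T),

and a phase-space point (Q, P) is then drawn from the Wigner function of
that level.  In dimensionless oscillator units (x, p) the level-n Wigner
function is

    W_n(x, p) = ((-1)^n / pi) L_n(2 r^2) exp(-r^2),   r^2 = x^2 + p^2,

which is partly negative for n >= 1; sampling uses rejection restricted to
the positive region (normalizing over it), the standard pragmatic choice in
initial-condition generators.  The ground state is a Gaussian and is drawn
directly.

The module also provides the diagnostics for the *shearing artifact*: a
torsional mode represented as a linear normal-mode displacement moves atoms
on straight lines instead of arcs, which stretches the rotating group by
1/cos(theta - theta_eq) — exposed by :func:`shear_width_profile` versus the
:func:`rigid_rotation_profile` control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_laguerre

from .normalmodes import NormalModeSet
from .system import InternalCoordinate, Snapshot, evaluate_internal
from .units import HBAR_AMU_A2_FS, KB, HC_EV_CM, omega_from_wavenumber

__all__ = [
    "WignerSpec",
    "ConformerSpec",
    "boltzmann_level_probability",
    "boltzmann_select_level",
    "sample_wigner",
    "sample_conformer_union",
    "shear_width_profile",
    "rigid_rotation_profile",
]


@dataclass
class WignerSpec:
    """Sampling temperature, excluded modes, level cap and seed.

    ``max_level`` bounds the vibrational quantum number per mode (rejection
    cost grows with n); for classical-limit modes (h c nu << k_B T) it must
    be raised well above k_B T / (h c nu) for the thermal variance to be
    faithful.
    """

    temperature: float = 300.0
    excluded_modes: frozenset[int] = frozenset()
    max_level: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_level < 0:
            raise ValueError("max_level must be >= 0")


@dataclass
class ConformerSpec:
    """One conformer in a multi-minimum union: modes + weight or count."""

    modes: NormalModeSet
    count: int | None = None
    weight: float | None = None
    energy: float | None = None  # eV relative to the lowest minimum
    label: str = ""


def boltzmann_level_probability(wavenumber_cm: float, temperature: float, n: int) -> float:
    """P(n) of the harmonic-oscillator Boltzmann distribution."""
    if temperature == 0.0:
        return 1.0 if n == 0 else 0.0
    beta_quantum = HC_EV_CM * wavenumber_cm / (KB * temperature)
    q = np.exp(-beta_quantum)
    return float((1.0 - q) * q**n)


def boltzmann_select_level(
    wavenumber_cm: float,
    temperature: float,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
    max_level: int | None = None,
):
    """Draw vibrational level(s) from the Boltzmann distribution.

    Uses inverse-CDF sampling of the (optionally truncated) geometric
    distribution, so results are exactly reproducible from the generator
    state.  T = 0 returns the ground state surely.
    """
    if wavenumber_cm <= 0:
        raise ValueError("wavenumber must be positive (no imaginary modes)")
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    shape = () if size is None else (size,)
    if temperature == 0.0:
        levels = np.zeros(shape, dtype=int)
        return int(levels) if size is None else levels
    q = np.exp(-HC_EV_CM * wavenumber_cm / (KB * temperature))
    u = rng.random(shape)
    if max_level is not None:
        u = u * (1.0 - q ** (max_level + 1))
    levels = np.floor(np.log1p(-u) / np.log(q)).astype(int)
    if max_level is not None:
        levels = np.minimum(levels, max_level)
    return int(levels) if size is None else levels


_WMAX_CACHE: dict[int, float] = {}


def _wigner_value(n: int, rsq: np.ndarray) -> np.ndarray:
    return (-1.0) ** n * eval_laguerre(n, 2.0 * rsq) * np.exp(-rsq)


def _wigner_max(n: int) -> float:
    """Max of the positive part of the (unnormalized) level-n Wigner function."""
    if n not in _WMAX_CACHE:
        r = np.linspace(0.0, np.sqrt(2 * n + 1) + 4.0, 4000)
        _WMAX_CACHE[n] = float(np.maximum(_wigner_value(n, r**2), 0.0).max()) * 1.001
    return _WMAX_CACHE[n]


#: above this level, sampling switches from positive-region rejection to the
#: semiclassical ring r^2 = 2n+1.  The restriction to the positive Wigner
#: region biases coordinate/momentum variances low (e.g. by a factor 5/6 at
#: n=1), and the bias would accumulate over the many levels populated in
#: classical-limit modes, breaking the thermal coth(hw/2kT) variance law;
#: the ring carries the exact second moments of every level and is the
#: large-n limit of the Wigner function, so a low threshold keeps the
#: thermal ensemble faithful where many levels contribute.
RING_LEVEL_THRESHOLD = 8


def _sample_wigner_xp(n: int, size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless (x, p) samples from the level-n Wigner function."""
    if n == 0:
        xy = rng.normal(scale=np.sqrt(0.5), size=(2, size))
        return xy[0], xy[1]
    if n > RING_LEVEL_THRESHOLD:
        r = np.sqrt(2.0 * n + 1.0)
        phase = rng.uniform(0.0, 2.0 * np.pi, size)
        return r * np.cos(phase), r * np.sin(phase)
    rmax = np.sqrt(2 * n + 1) + 4.0
    wmax = _wigner_max(n)
    xs = np.empty(size)
    ps = np.empty(size)
    filled = 0
    while filled < size:
        batch = max(4 * (size - filled), 1024)
        x = rng.uniform(-rmax, rmax, batch)
        p = rng.uniform(-rmax, rmax, batch)
        w = _wigner_value(n, x**2 + p**2)
        accept = rng.uniform(0.0, wmax, batch) < w
        take = min(int(accept.sum()), size - filled)
        xs[filled : filled + take] = x[accept][:take]
        ps[filled : filled + take] = p[accept][:take]
        filled += take
    return xs, ps


def sample_wigner(
    modes: NormalModeSet,
    spec: WignerSpec,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> list[Snapshot]:
    """Draw phase-space samples from the finite-temperature Wigner ensemble.

    Returns snapshots (stage ``"wigner"``) whose positions/velocities are the
    reference geometry plus the per-mode displacements; excluded modes
    contribute nothing.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    bad = [i for i in range(modes.n_modes) if i not in spec.excluded_modes and modes.wavenumbers[i] <= 0]
    if bad:
        raise ValueError(f"imaginary/zero frequencies among included modes: {bad}")
    if any(i < 0 or i >= modes.n_modes for i in spec.excluded_modes):
        raise ValueError("excluded mode index out of range")

    n_atoms = modes.n_atoms
    sqm = np.sqrt(modes.masses)[:, None]
    dr = np.zeros((n_samples, n_atoms, 3))
    dv = np.zeros((n_samples, n_atoms, 3))
    level_record = np.zeros((n_samples, modes.n_modes), dtype=int)

    for i in range(modes.n_modes):
        if i in spec.excluded_modes:
            continue
        omega = omega_from_wavenumber(modes.wavenumbers[i])  # rad/fs
        levels = boltzmann_select_level(
            modes.wavenumbers[i], spec.temperature, rng, size=n_samples,
            max_level=spec.max_level,
        )
        level_record[:, i] = levels
        x = np.empty(n_samples)
        p = np.empty(n_samples)
        for n_level in np.unique(levels):
            mask = levels == n_level
            xs, ps = _sample_wigner_xp(int(n_level), int(mask.sum()), rng)
            x[mask] = xs
            p[mask] = ps
        q_scale = np.sqrt(HBAR_AMU_A2_FS / omega)  # amu^1/2 A
        p_scale = np.sqrt(HBAR_AMU_A2_FS * omega)  # amu^1/2 A / fs
        cart = modes.modes[i] / sqm  # displacement per unit Q
        dr += (x * q_scale)[:, None, None] * cart[None]
        dv += (p * p_scale)[:, None, None] * cart[None]

    snapshots = []
    for s in range(n_samples):
        snapshots.append(
            Snapshot(
                positions=modes.reference + dr[s],
                velocities=dv[s],
                stage="wigner",
                meta={"levels": level_record[s].copy()},
            )
        )
    return snapshots


def _counts_from_weights(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of weights to integer counts summing to total."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("conformer weights must be >= 0 with at least one positive")
    frac = weights / weights.sum() * total
    counts = np.floor(frac).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(frac - counts))
    counts[order[:remainder]] += 1
    return counts


def sample_conformer_union(
    conformers: list[ConformerSpec],
    wigner_spec: WignerSpec,
    total: int | None = None,
) -> list[Snapshot]:
    """Union of Wigner ensembles over several minima.

    Per-conformer counts honour explicit ``count`` fields; otherwise they are
    derived from ``weight`` (or Boltzmann factors ``exp(-E/kT)`` when only
    relative ``energy`` values are given) by largest-remainder rounding to
    ``total``.  Each snapshot is tagged with its source conformer label.
    """
    if not conformers:
        raise ValueError("no conformers given")
    explicit = [c.count for c in conformers]
    if all(c is not None for c in explicit):
        counts = np.array(explicit, dtype=int)
    else:
        if total is None:
            raise ValueError("total ensemble size required when using weights")
        weights = []
        for c in conformers:
            if c.weight is not None:
                weights.append(c.weight)
            elif c.energy is not None:
                if wigner_spec.temperature <= 0:
                    raise ValueError("Boltzmann weights need a positive temperature")
                weights.append(np.exp(-c.energy / (KB * wigner_spec.temperature)))
            else:
                raise ValueError("conformer needs count, weight or energy")
        counts = _counts_from_weights(np.array(weights), total)

    rng = np.random.default_rng(wigner_spec.seed)
    ensemble: list[Snapshot] = []
    for conf, count in zip(conformers, counts):
        snaps = sample_wigner(conf.modes, wigner_spec, int(count), rng=rng)
        for s in snaps:
            s.meta["conformer"] = conf.label or "conformer"
        ensemble.extend(snaps)
    return ensemble


def shear_width_profile(
    modes: NormalModeSet,
    torsion_mode_index: int,
    torsion: InternalCoordinate,
    marker_pair: tuple[int, int],
    displacements: np.ndarray,
) -> np.ndarray:
    """Profile of (apparent torsion angle, marker width) along a linear mode.

    Displaces the reference geometry linearly along the chosen (mass-weighted)
    normal-mode vector by each normal-coordinate value in ``displacements``
    (amu^1/2 A) and records the torsion angle and the marker-atom distance.
    On a rigid planar rotor the width follows w_eq / cos(theta - theta_eq):
    the mode *shears* the rotor instead of rotating it.

    Returns an array of shape (len(displacements), 2): [theta_deg, width_A].
    """
    if not 0 <= torsion_mode_index < modes.n_modes:
        raise IndexError("torsion mode index out of range")
    i, j = marker_pair
    cart = modes.modes[torsion_mode_index] / np.sqrt(modes.masses)[:, None]
    width_coord = InternalCoordinate("distance", (i, j), "marker-width")
    out = np.empty((len(displacements), 2))
    for k, q in enumerate(np.asarray(displacements, dtype=float)):
        pos = modes.reference + q * cart
        out[k, 0] = evaluate_internal(torsion, pos)
        out[k, 1] = evaluate_internal(width_coord, pos)
    return out


def rigid_rotation_profile(
    reference: np.ndarray,
    axis_atoms: tuple[int, int],
    rotating_atoms: list[int],
    torsion: InternalCoordinate,
    marker_pair: tuple[int, int],
    angles_deg: np.ndarray,
) -> np.ndarray:
    """Control for :func:`shear_width_profile`: rotate the group rigidly.

    Rotates ``rotating_atoms`` about the axis through the two axis atoms by
    each angle; a true rotation leaves all internal distances of the group
    unchanged, so the marker width stays constant over the whole profile.
    """
    reference = np.asarray(reference, dtype=float)
    a, b = axis_atoms
    axis = reference[b] - reference[a]
    axis = axis / np.linalg.norm(axis)
    origin = reference[a]
    width_coord = InternalCoordinate("distance", tuple(marker_pair), "marker-width")
    out = np.empty((len(angles_deg), 2))
    for k, ang in enumerate(np.radians(np.asarray(angles_deg, dtype=float))):
        pos = reference.copy()
        rel = pos[rotating_atoms] - origin
        cos, sin = np.cos(ang), np.sin(ang)
        # Rodrigues rotation
        rot = (
            rel * cos
            + np.cross(np.broadcast_to(axis, rel.shape), rel) * sin
            + np.outer(rel @ axis, axis) * (1.0 - cos)
        )
        pos[rotating_atoms] = origin + rot
        out[k, 0] = evaluate_internal(torsion, pos)
        out[k, 1] = evaluate_internal(width_coord, pos)
    return out
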