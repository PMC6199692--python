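"""Ensemble diagnostics: Gaussian fits, effective temperatures, conformers.

* Internal-coordinate histograms are fit with least-squares Gaussians
  (Scott's-rule binning by default, bin centers weighted by Poisson errors).
* Per-atom effective temperatures come from fits of the Maxwell-Boltzmann
  kinetic-energy density

      f(E) = 2 sqrt(E / pi) (k_B T)^(-3/2) exp(-E / k_B T)

  to kinetic-energy histograms, with the moment identity
  T = (2/3) <E> / k_B available as a closed-form cross-check.
* ZPE accounting converts a total vibrational energy into the classical
  temperature whose equipartition energy matches it, T = E / (n_dof k_B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .normalmodes import NormalModeSet
from .units import KB
from .system import wrap_angle_deg

__all__ = [
    "GaussianFitResult",
    "EffectiveTemperature",
    "ZPEAccount",
    "fit_gaussian_histogram",
    "fit_effective_temperature",
    "classify_conformer",
    "zpe_target_temperature",
    "correlation_scan",
]


@dataclass
class GaussianFitResult:
    """Least-squares Gaussian fit of a histogram."""

    mean: float
    std: float
    amplitude: float
    residual: float  # rms residual relative to the peak count
    mean_err: float = float("nan")
    std_err: float = float("nan")
    bin_width: float = float("nan")

    #: relative rms residual above which the fit is considered poor
    POOR_THRESHOLD = 0.15

    @property
    def is_poor(self) -> bool:
        return bool(self.residual > self.POOR_THRESHOLD)


@dataclass
class EffectiveTemperature:
    atom_index: int
    temperature: float  # K
    uncertainty: float  # K
    method: str  # "histogram-fit" | "closed-form"

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("effective temperature must be >= 0")


@dataclass
class ZPEAccount:
    """Per-mode ZPE bookkeeping with an optional exclusion set.

    ``n_internal_dof`` defaults to 3N-6 for the nonlinear molecule the modes
    describe (pass explicitly for linear systems).
    """

    wavenumbers: np.ndarray  # cm^-1
    zpe_per_mode: np.ndarray  # eV
    n_internal_dof: int
    excluded: frozenset[int] = frozenset()

    @classmethod
    def from_modes(cls, modes: NormalModeSet, excluded: frozenset[int] = frozenset()) -> "ZPEAccount":
        return cls(
            wavenumbers=modes.wavenumbers.copy(),
            zpe_per_mode=modes.zpe_per_mode(),
            n_internal_dof=modes.n_modes,
            excluded=excluded,
        )

    @property
    def total_zpe(self) -> float:
        return float(
            sum(z for i, z in enumerate(self.zpe_per_mode) if i not in self.excluded)
        )


def scott_bin_width(values: np.ndarray) -> float:
    """Scott's rule: h = 3.49 sigma n^(-1/3)."""
    values = np.asarray(values, dtype=float)
    sigma = float(np.std(values))
    if sigma == 0.0:
        raise ValueError("degenerate (all-equal) values")
    return 3.49 * sigma * values.size ** (-1.0 / 3.0)


def _gauss(x, amplitude, mean, std):
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * std**2))


def fit_gaussian_histogram(
    values: np.ndarray, bin_width: float | None = None
) -> GaussianFitResult:
    """Histogram the values and least-squares fit a Gaussian to the counts.

    Bin centers are weighted by Poisson errors sqrt(max(count, 1)).  Requires
    at least 20 values; raises on degenerate (all-equal) input.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 20:
        raise ValueError("need at least 20 values for a histogram fit")
    if np.ptp(values) == 0.0:
        raise ValueError("degenerate (all-equal) values")
    if bin_width is None:
        bin_width = scott_bin_width(values)
    lo, hi = values.min(), values.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 5)
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma = np.sqrt(np.maximum(counts, 1.0))
    p0 = (float(counts.max()), float(values.mean()), float(values.std()))
    try:
        popt, pcov = curve_fit(
            _gauss, centers, counts, p0=p0, sigma=sigma, absolute_sigma=True, maxfev=10000
        )
    except RuntimeError as exc:
        raise ValueError(f"Gaussian fit did not converge: {exc}") from exc
    perr = np.sqrt(np.abs(np.diag(pcov)))
    fit = _gauss(centers, *popt)
    residual = float(np.sqrt(np.mean((fit - counts) ** 2)) / max(counts.max(), 1))
    return GaussianFitResult(
        mean=float(popt[1]),
        std=float(abs(popt[2])),
        amplitude=float(popt[0]),
        residual=residual,
        mean_err=float(perr[1]),
        std_err=float(perr[2]),
        bin_width=float(bin_width),
    )


def maxwell_boltzmann_pdf(e: np.ndarray, temperature: float) -> np.ndarray:
    """Maxwell-Boltzmann kinetic-energy density (per eV) at ``temperature``."""
    kt = KB * temperature
    e = np.asarray(e, dtype=float)
    return 2.0 * np.sqrt(np.maximum(e, 0.0) / np.pi) * kt**-1.5 * np.exp(-e / kt)


def fit_effective_temperature(
    kinetic_energies: np.ndarray,
    atom_index: int = 0,
    method: str = "histogram-fit",
    bins: int | None = None,
) -> EffectiveTemperature:
    """Effective temperature of one atom from its kinetic-energy samples.

    ``method="histogram-fit"`` (default, matching how effective temperatures
    are usually quoted) least-squares fits the Maxwell-Boltzmann density to a
    normalized histogram; ``method="closed-form"`` uses the exact moment
    identity T = (2/3) <E> / k_B with its standard-error propagated.
    """
    e = np.asarray(kinetic_energies, dtype=float)
    if e.size < 100:
        raise ValueError("need at least 100 kinetic-energy samples")
    if np.all(e == 0.0):
        raise ValueError("all kinetic energies are zero")
    t_moment = 2.0 * float(e.mean()) / (3.0 * KB)
    if method == "closed-form":
        unc = 2.0 * float(e.std(ddof=1)) / (3.0 * KB * np.sqrt(e.size))
        return EffectiveTemperature(atom_index, t_moment, unc, "closed-form")
    if method != "histogram-fit":
        raise ValueError(f"unknown method {method!r}")
    if bins is None:
        bins = max(int(np.sqrt(e.size)), 10)
    counts, edges = np.histogram(e, bins=bins)
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # Poisson weights sigma_i ~ sqrt(count); zero-count bins carry no
    # information about the density and are dropped rather than floored
    # (flooring them biases the tail, and hence T, low)
    occupied = counts > 0
    density = counts[occupied] / (e.size * widths[occupied])
    centers = centers[occupied]
    sigma = np.sqrt(counts[occupied]) / (e.size * widths[occupied])
    try:
        popt, pcov = curve_fit(
            maxwell_boltzmann_pdf, centers, density, p0=(t_moment,),
            sigma=sigma, absolute_sigma=True, maxfev=10000
        )
    except RuntimeError as exc:
        raise ValueError(f"Maxwell-Boltzmann fit did not converge: {exc}") from exc
    unc = float(np.sqrt(np.abs(pcov[0, 0])))
    return EffectiveTemperature(atom_index, float(popt[0]), unc, "histogram-fit")


def classify_conformer(theta_deg: float) -> str:
    """Torsional conformer label from the torsion angle.

    B (parallel) for |theta| < 45 deg; A for theta in [-135, -45]; A' for
    [45, 135]; the wraparound region |theta| > 135 is assigned to the
    nearer of A / A' by angular distance.
    """
    theta = float(wrap_angle_deg(theta_deg))
    if abs(theta) < 45.0:
        return "B"
    if -135.0 <= theta <= -45.0:
        return "A"
    if 45.0 <= theta <= 135.0:
        return "A'"
    # wraparound: distance to -90 vs +90 through 180
    return "A" if theta < 0 else "A'"


def zpe_target_temperature(account: ZPEAccount, rounding: str | None = None) -> float:
    """Classical temperature equivalent to a vibrational energy budget.

    T = E_total / (n_dof k_B): the temperature at which a classical
    equipartition ensemble would carry the same internal energy as the
    (possibly truncated) zero-point sum.  ``rounding="nearest-100"``
    reproduces the conventional reporting granularity.
    """
    total = account.total_zpe
    if total <= 0:
        raise ValueError("total ZPE must be positive")
    if account.n_internal_dof <= 0:
        raise ValueError("DOF count must be positive")
    t = total / (account.n_internal_dof * KB)
    if rounding == "nearest-100":
        return float(round(t / 100.0) * 100.0)
    if rounding is not None:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return t


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    table: pd.DataFrame = field(repr=False, default=None)

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI excludes zero."""
        return bool(self.ci_low > 0.0 or self.ci_high < 0.0)


def correlation_scan(
    x: np.ndarray,
    y: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    names: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Pearson correlation with a bootstrap confidence interval.

    Returns the coefficient, its percentile 95% CI over ``n_bootstrap``
    resamples, and the scatter table (for plotting / export).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 30:
        raise ValueError("need two equal-length arrays with at least 30 samples")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined for a constant coordinate")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_bootstrap, x.size))
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        xb = x[idx[b]]
        yb = y[idx[b]]
        if np.std(xb) == 0.0 or np.std(yb) == 0.0:
            boots[b] = np.nan
            continue
        boots[b] = np.corrcoef(xb, yb)[0, 1]
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    table = pd.DataFrame({names[0]: x, names[1]: y})
    return CorrelationResult(r=r, ci_low=float(lo), ci_high=float(hi), n=int(x.size), table=table)
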