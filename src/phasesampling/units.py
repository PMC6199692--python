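"""Internal unit system and physical constants.

Everything inside the package works in a single unit system

===========  =========
quantity     unit
===========  =========
length       angstrom (A)
time         femtosecond (fs)
mass         atomic mass unit (amu)
energy       electronvolt (eV)
temperature  kelvin (K)
charge       elementary charge (e)
===========  =========

All file readers/writers convert at the boundary.  The kinetic energy of a
particle is therefore ``0.5 * m * v**2 * AMU_A2_FS2_TO_EV`` with ``m`` in amu
and ``v`` in A/fs.

A useful identity that the constant set must reproduce: the classical thermal
energy per mode at 300 K, k_B * 300 K = 25.85 meV, equals the zero-point
energy of a harmonic mode at 417 cm^-1 (0.5 * h*c * 417 cm^-1).
"""

from __future__ import annotations

import math

#: Boltzmann constant, eV / K (CODATA 2018, exact)
KB = 8.617333262e-5

#: Planck constant times speed of light, eV * cm
HC_EV_CM = 1.239841984e-4

#: Reduced Planck constant, eV * fs
HBAR_EV_FS = 0.6582119569

#: Speed of light, cm / fs
C_CM_FS = 2.99792458e-5

#: 1 amu * A^2 / fs^2 expressed in eV
AMU_A2_FS2_TO_EV = 1.0364269574711572e2

#: 1 eV expressed in amu * A^2 / fs^2
EV_TO_AMU_A2_FS2 = 1.0 / AMU_A2_FS2_TO_EV

#: hbar expressed in amu * A^2 / fs (mass-weighted-coordinate actions)
HBAR_AMU_A2_FS = HBAR_EV_FS * EV_TO_AMU_A2_FS2

#: Coulomb constant e^2/(4 pi eps0), eV * A
COULOMB_EV_A = 14.399645478

#: Bohr radius, A
BOHR_TO_A = 0.529177210903

#: 1 kcal/mol in eV
KCAL_MOL_TO_EV = 4.3364104350e-2


def kinetic_energy(mass_amu: float, speed_a_fs: float) -> float:
    """Kinetic energy (eV) of a point mass, 0.5 m v^2."""
    return 0.5 * mass_amu * speed_a_fs**2 * AMU_A2_FS2_TO_EV


def omega_from_wavenumber(wavenumber_cm: float) -> float:
    """Angular frequency (rad/fs) of a mode given its wavenumber in cm^-1."""
    return 2.0 * math.pi * C_CM_FS * wavenumber_cm


def wavenumber_from_omega(omega_fs: float) -> float:
    """Wavenumber (cm^-1) from angular frequency in rad/fs."""
    return omega_fs / (2.0 * math.pi * C_CM_FS)


def zpe_from_wavenumber(wavenumber_cm: float) -> float:
    """Harmonic zero-point energy (eV), 0.5 h c nu-tilde."""
    return 0.5 * HC_EV_CM * wavenumber_cm


def thermal_quantum_ratio(wavenumber_cm: float, temperature_k: float) -> float:
    """h c nu-tilde / (k_B T): vibrational quantum over thermal energy."""
    if temperature_k <= 0.0:
        return math.inf
    return HC_EV_CM * wavenumber_cm / (KB * temperature_k)
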