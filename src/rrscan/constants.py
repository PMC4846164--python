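"""Physical constants and the internal unit system.

Internal mechanical units are amu, Å, ps (the natural units of biomolecular
trajectories): energies then come out in amu·Å²/ps², and one kcal/mol is
``KCAL_MOL_IN_INTERNAL`` of those. Quasi-harmonic frequencies are angular
(rad/ps) internally and reported as wavenumbers (cm⁻¹).
"""

import numpy as np

#: Boltzmann constant, kcal/(mol·K).
KB_KCAL = 1.987204e-3

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Atomic mass unit, kg.
AMU_KG = 1.66053906660e-27

#: Reduced Planck constant, J·s.
HBAR_JS = 1.054571817e-34

#: Speed of light, cm/ps.
C_CM_PER_PS = 2.99792458e-2

#: 1 kcal/mol expressed in amu·Å²/ps² (≈ 418.4).
KCAL_MOL_IN_INTERNAL = (4184.0 / AVOGADRO) / (AMU_KG * 1e4)

#: ħ in kcal·ps/mol, for ħω/(k_B T) with ω in rad/ps.
HBAR_KCAL_PS = HBAR_JS * AVOGADRO * 1e12 / 4184.0

#: Default analysis temperature, K (canonical-ensemble simulation temperature).
DEFAULT_TEMPERATURE = 300.0


def kbt_internal(temperature: float) -> float:
    """k_B·T in internal units (amu·Å²/ps²)."""
    return KB_KCAL * temperature * KCAL_MOL_IN_INTERNAL


def omega_to_wavenumber(omega_per_ps: np.ndarray | float) -> np.ndarray | float:
    """Angular frequency (rad/ps) to wavenumber ν̃ = ω/(2πc) in cm⁻¹."""
    return omega_per_ps / (2.0 * np.pi * C_CM_PER_PS)


def wavenumber_to_omega(nu_cm1: np.ndarray | float) -> np.ndarray | float:
    """Wavenumber (cm⁻¹) back to angular frequency in rad/ps."""
    return nu_cm1 * 2.0 * np.pi * C_CM_PER_PS
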