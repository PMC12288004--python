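"""Internal unit system and physical constants.

The package works throughout in the "AKMA-like" unit system common to
biomolecular force fields:

========  ==========================
energy    kcal/mol
length    angstrom (A)
time      femtosecond (fs)
mass      atomic mass unit (amu)
charge    elementary charge (e)
========  ==========================

All constants below are derived at import time from CODATA values in
:mod:`scipy.constants` rather than hard-coded, so the unit conversions are
exact to the precision of the underlying constants.
"""

from __future__ import annotations

from scipy import constants as _c

#: Joules per thermochemical kilocalorie.
_J_PER_KCAL = _c.calorie * 1000.0

#: 1 kcal/mol expressed in the internal dynamical energy unit amu * A^2 / fs^2.
#: Derivation: (4184 J / N_A) per molecule, with 1 amu*A^2/fs^2 =
#: m_u[kg] * (1e-10 m)^2 / (1e-15 s)^2 = m_u * 1e10 J.  Numerically ~4.184e-4.
KCAL_MOL_TO_INTERNAL = (_J_PER_KCAL / _c.Avogadro) / (_c.atomic_mass * 1.0e10)

#: Inverse conversion: amu * A^2 / fs^2 -> kcal/mol (~2390.06).
INTERNAL_TO_KCAL_MOL = 1.0 / KCAL_MOL_TO_INTERNAL

#: Coulomb constant e^2/(4 pi eps0) in kcal*A/(mol*e^2)  (~332.0637).
COULOMB_CONSTANT = (
    _c.e**2 / (4.0 * _c.pi * _c.epsilon_0 * 1.0e-10) * _c.Avogadro / _J_PER_KCAL
)

#: Boltzmann constant in kcal/(mol*K)  (~1.98720e-3); equals R in these units.
BOLTZMANN_KCAL_MOL = _c.R / _J_PER_KCAL


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KCAL_MOL * temperature
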