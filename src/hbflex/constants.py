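"""Physical constants and unit conventions used throughout the package.

Internal mechanical units are kcal mol^-1 and Angstrom; temperatures are
Kelvin.  Thermodynamic (calorimetric) quantities use kJ mol^-1.
"""

from __future__ import annotations

#: Boltzmann constant in kcal mol^-1 K^-1 (i.e. the molar gas constant
#: expressed in kcal).  k_B * 300 K ~ 0.596 kcal mol^-1.
KB_KCAL: float = 1.987204259e-3

#: Molar gas constant in kJ mol^-1 K^-1, used by the van't Hoff analysis.
R_KJ: float = 8.31446261815324e-3

#: Avogadro's number, mol^-1.
N_AVOGADRO: float = 6.02214076e23

#: Thermochemical calorie, J.
CAL_J: float = 4.184

#: 1 kcal mol^-1 A^-2 expressed in N m^-1 (~0.695).
KCAL_MOL_A2_IN_N_M: float = (1e3 * CAL_J / N_AVOGADRO) / 1e-20

#: Celsius offset.
T0_CELSIUS: float = 273.15

# ---------------------------------------------------------------------------
# Linked conventions for the elastic-scattering analysis.
#
# The Gaussian approximation can be written with the mean square displacement
# entering the elastic intensity as exp(-<u2> q^2 / 6) (full 3-D MSD) or as
# exp(-<u2> q^2 / 3) (displacement-from-mean convention); each pairing has its
# own numerical constant in the resilience relation <k'> = C_k / (d<u2>/dT).
# The divisor and the constant must always be switched together, so they are
# shipped as linked pairs keyed by the divisor.
# ---------------------------------------------------------------------------

#: Map Gaussian exponent divisor -> force-constant numerator C_k such that
#: <k'> is in N m^-1 when d<u2>/dT is in A^2 K^-1.
RESILIENCE_CONSTANT: dict[int, float] = {6: 0.00276, 3: 0.00138}

#: Default Gaussian exponent divisor (full 3-D MSD convention).
DEFAULT_GAUSSIAN_DIVISOR: int = 6

#: Validity bound of the Gaussian approximation: flag fits with
#: <u2> * q2_max above this value.
GAUSSIAN_VALIDITY_BOUND: float = 2.0


def kcal_mol_A2_to_N_m(k: float) -> float:
    """Convert a force constant from kcal mol^-1 A^-2 to N m^-1.

    Examples
    --------
    >>> round(kcal_mol_A2_to_N_m(0.6), 2)
    0.42
    >>> round(kcal_mol_A2_to_N_m(1.0), 1)
    0.7
    """
    return k * KCAL_MOL_A2_IN_N_M


def N_m_to_kcal_mol_A2(k: float) -> float:
    """Inverse of :func:`kcal_mol_A2_to_N_m`."""
    return k / KCAL_MOL_A2_IN_N_M


def celsius_to_kelvin(t: float) -> float:
    return t + T0_CELSIUS


def kelvin_to_celsius(t: float) -> float:
    return t - T0_CELSIUS
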