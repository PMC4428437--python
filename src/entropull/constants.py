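"""Physical constants and unit conversions.

All model energies are expressed in units of k_BT.  Temperature enters the
pipeline only when free-energy slopes (k_BT per residue) are converted to
mechanical forces in piconewton.  The conversion constant is evaluated from
CODATA values at import time rather than hard-coded.
"""

import scipy.constants as _sc

#: Boltzmann constant, J/K
K_BOLTZMANN = _sc.k

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0

#: Contour length per residue of an extended polypeptide, Angstrom
RESIDUE_CONTOUR_A = 3.8


def kBT_in_pN_A(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_BT expressed in pN*Angstrom (1 pN*A = 1e-22 J)."""
    return K_BOLTZMANN * temperature / 1e-22


def force_pN_per_kT_slope(temperature: float = DEFAULT_TEMPERATURE,
                          contour_a: float = RESIDUE_CONTOUR_A) -> float:
    """Force in pN produced by a free-energy slope of 1 k_BT per residue.

    A slope of s k_BT/residue along the import coordinate corresponds to a
    mechanical force s * k_BT / (contour length per residue).
    """
    return kBT_in_pN_A(temperature) / contour_a
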