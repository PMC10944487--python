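"""Physical constants and unit-conversion factors, derived once from CODATA.

Unit contract used throughout the package:

* distances in Å
* charges in units of the elementary charge e
* transition dipoles in Debye
* energies, couplings, site energies and lineshape widths in cm⁻¹
* rates in ps⁻¹, time constants in ps

Every derived conversion factor below is computed from ``scipy.constants``
(CODATA) at import time; nothing is duplicated elsewhere. Output files embed
:data:`CONSTANTS_VERSION` so results can be traced to the constant set used.
"""

from __future__ import annotations

import math

from scipy import constants as _codata

CONSTANTS_VERSION = "eetkit-constants-1 (scipy CODATA)"

#: J per cm⁻¹ (h·c with c in cm/s); used to express energies in wavenumbers.
_J_PER_CM1 = _codata.h * _codata.c * 100.0

#: 1 Debye in C·m (the Debye is 1e-18 statC·cm; with c in m/s this is 1e-21/c).
_DEBYE_CM = 1e-21 / _codata.c

#: 1 e·Å expressed in Debye (≈ 4.8032).
EA_TO_DEBYE = _codata.e * 1e-10 / _DEBYE_CM

#: Coulomb coupling constant: e²/(4πε₀·Å) expressed in cm⁻¹ (≈ 1.1614e5).
#: V[cm⁻¹] = K_COUL · Σ q_l q_l' / R_ll' with q in e and R in Å.
K_COUL_CM1 = _codata.e**2 / (4.0 * math.pi * _codata.epsilon_0 * 1e-10) / _J_PER_CM1

#: Dipole–dipole coupling constant: Debye²/Å³ expressed in cm⁻¹ (≈ 5034).
#: V[cm⁻¹] = K_DD · κ · μ_m μ_n / R³ with μ in Debye and R in Å.
K_DD_CM1 = K_COUL_CM1 / EA_TO_DEBYE**2

#: ħ expressed in cm⁻¹·s (≈ 5.3089e-12).
HBAR_CM1_S = _codata.hbar / _J_PER_CM1

#: Rate prefactor 2π/ħ arranged so that (cm⁻¹)² · (cm⁻¹)⁻¹ → ps⁻¹ (≈ 1.1836).
#: T[ps⁻¹] = C_RATE · V[cm⁻¹]² · J[(cm⁻¹)⁻¹].
C_RATE_PS = 2.0 * math.pi / HBAR_CM1_S * 1e-12

#: Boltzmann constant in cm⁻¹ per kelvin (≈ 0.695035).
K_B_CM1 = _codata.k / _J_PER_CM1

#: σ = FWHM / FWHM_PER_SIGMA for a Gaussian (2·√(2 ln 2) ≈ 2.3548).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
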