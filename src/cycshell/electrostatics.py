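"""Debye screening-length arithmetic for electrolyte solutions."""

from __future__ import annotations

import math

from scipy import constants

from .core import DomainError


def debye_length(ion_species, temperature: float = 298.0,
                 relative_permittivity: float = 78.4) -> float:
    """Debye length kappa^-1 in Å.

    ``ion_species`` lists (molar concentration, valence) pairs — e.g. 1 M
    NaCl is ``[(1.0, +1), (1.0, -1)]``.  Uses

        kappa^-1 = sqrt( eps0 * eps_r * kB * T / (2 * NA * e^2 * Ic) )

    with ionic strength Ic = 1/2 * sum c_i z_i^2 converted to mol/m^3.  The
    default permittivity is that of water near 298 K; kappa^-1 scales as
    Ic^(-1/2) exactly.
    """
    if temperature <= 0 or relative_permittivity <= 0:
        raise DomainError("temperature and permittivity must be positive")
    ionic_strength = 0.0
    for conc, z in ion_species:
        if conc < 0:
            raise DomainError("concentrations must be >= 0")
        ionic_strength += 0.5 * conc * z * z
    if ionic_strength == 0:
        raise DomainError("at least one ion concentration must be nonzero")
    ic = ionic_strength * 1000.0  # mol/L -> mol/m^3
    kappa_sq_inv = (constants.epsilon_0 * relative_permittivity
                    * constants.k * temperature
                    / (2.0 * constants.N_A * constants.e ** 2 * ic))
    return math.sqrt(kappa_sq_inv) * 1e10


def nacl_species(concentration: float):
    """(c, z) pairs for a 1:1 NaCl solution at the given molarity."""
    return [(concentration, 1), (concentration, -1)]
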