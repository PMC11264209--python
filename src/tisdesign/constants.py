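"""Physical constants and unit conventions.

All public interfaces use kcal/mol (energy), Angstrom (length), femtosecond
(time), amu (mass), and Kelvin (temperature).  Internally, accelerations are
obtained by converting kcal/mol to the consistent dynamical energy unit
amu*A^2/fs^2.
"""

# 1 kcal/mol expressed in amu*A^2/fs^2.
# amu*A^2/fs^2 = (1e-3 kg/mol)(1e-20 m^2)(1e30 s^-2) = 1e7 J/mol exactly,
# so the factor is 4184 / 1e7.
KCAL_PER_MOL_TO_INTERNAL = 4.184e-4

# Boltzmann constant, kcal/(mol*K)  (CODATA k_B * N_A / 4184)
KB_KCAL = 1.987204259e-3

# Boltzmann and Planck constants (SI), for the Eyring prefactor k_B*T/h.
KB_SI = 1.380649e-23     # J/K
PLANCK_SI = 6.62607015e-34  # J*s

DEFAULT_TEMPERATURE = 300.0  # K


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in kcal/mol."""
    return KB_KCAL * temperature


def kT_internal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy in amu*A^2/fs^2 (the integrator's unit system)."""
    return kT(temperature) * KCAL_PER_MOL_TO_INTERNAL
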