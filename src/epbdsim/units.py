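"""Unit system and physical constants.

The internal unit system is eV (energy), Angstrom (length) and amu (mass).
The derived internal time unit is

    t0 = sqrt(1 amu * 1 A**2 / 1 eV) = 10.1805 fs,

so a user-facing time step of 1 fs corresponds to ``1 / T0_FS`` internal
time units.  All user-facing durations are femtoseconds, picoseconds or
nanoseconds; conversion happens at the engine boundary only.
"""

import math

#: Boltzmann constant in eV/K.
KB_EV: float = 8.617333262e-5

# SI building blocks used once, to derive the internal time unit.
_AMU_KG = 1.66053906660e-27
_EV_J = 1.602176634e-19

#: Internal time unit in femtoseconds: sqrt(amu * A^2 / eV).
T0_FS: float = math.sqrt(_AMU_KG * 1e-20 / _EV_J) * 1e15

#: Femtoseconds per picosecond / nanosecond (for readable conversions).
FS_PER_PS: float = 1e3
FS_PER_NS: float = 1e6


def fs_to_internal(t_fs: float) -> float:
    """Convert a time in femtoseconds to internal time units."""
    return t_fs / T0_FS


def per_ps_to_internal(rate_per_ps: float) -> float:
    """Convert a rate (e.g. a friction coefficient) from ps^-1 to t0^-1."""
    return rate_per_ps * T0_FS / FS_PER_PS
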