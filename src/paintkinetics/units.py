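"""Unit conversions used across the package.

Internal convention: rates in SI (s^-1, M^-1 s^-1), concentrations in molar,
times in seconds, lengths in micrometers.  Nanomolar values are accepted and
produced only at interface boundaries, through the helpers below.
"""

from __future__ import annotations

#: molecules per µm^3 corresponding to a 1 nM solution (Avogadro constant
#: scaled: 6.0221e23 / L * 1e-9 M * 1e-15 L/µm^3)
MOLECULES_PER_UM3_PER_NM = 0.60221


def nM(value: float) -> float:
    """Convert a nanomolar concentration to molar."""
    return value * 1e-9


def to_nM(molar: float) -> float:
    """Convert a molar concentration to nanomolar."""
    return molar * 1e9


def per_um3_to_molar(number_density: float) -> float:
    """Convert a number density in molecules/µm³ to molar."""
    return nM(number_density / MOLECULES_PER_UM3_PER_NM)


def round_sig(value: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation helper)."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sig - 1))
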