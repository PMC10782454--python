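"""Unit conventions and physical constants.

All internal quantities are Hartree atomic units; Ångström is accepted at
I/O boundaries and converted exactly once.  NMR observables use the field's
customary mixed units: shieldings/shifts in ppm, scalar couplings J in Hz,
reduced couplings K in SI (T^2 J^-1 = kg m^-2 A^-2 s^-2... i.e. N A^-2 m^-3).
"""

from __future__ import annotations

from scipy import constants as _c

#: Bohr radii per Ångström (CODATA).
BOHR_PER_ANGSTROM: float = 1e-10 / _c.value("Bohr radius")
ANGSTROM_PER_BOHR: float = 1.0 / BOHR_PER_ANGSTROM

#: Planck constant, J s (exact, SI 2019).
PLANCK_H: float = _c.h

# Magnetogyric ratios, rad s^-1 T^-1.  1H is CODATA; the heteronuclei are
# not tabulated by CODATA and come from standard NMR reference tables
# (negative signs for 15N and 17O).
GYROMAGNETIC_RATIOS: dict[str, float] = {
    "1H": _c.value("proton gyromag. ratio"),
    "13C": 6.728284e7,
    "15N": -2.7126e7,
    "17O": -3.62808e7,
    "19F": 25.18148e7,
    "31P": 10.8394e7,
}

#: Default TMS isotropic shielding references (au of shielding, ppm scale).
SHIELDING_REFERENCES: dict[str, float] = {
    "1H": 31.7,
    "13C": 182.852,
}

_SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
}


def atomic_number(symbol: str) -> int:
    """Nuclear charge Z for a chemical symbol (common elements)."""
    try:
        return _SYMBOL_TO_Z[symbol.capitalize() if len(symbol) > 1 else symbol.upper()]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR
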