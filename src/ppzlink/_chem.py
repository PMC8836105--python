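"""Monoisotopic masses derived from molecular formulas.

All chemistry constants used by the cross-link search are computed here from
element masses and residue/linker molecular formulas, never hard-coded as
decimals.
"""

from __future__ import annotations

import re

# CODATA-style monoisotopic element masses (Da)
ELEMENT_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

PROTON = 1.00727646688

_FORMULA = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a molecular formula like ``C8H10O2``."""
    mass = 0.0
    pos = 0
    for m in _FORMULA.finditer(formula):
        if m.start() != pos or not m.group(0):
            break
        elem = m.group(1)
        if elem not in ELEMENT_MASS:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        mass += ELEMENT_MASS[elem] * (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return mass


# residue (= amino acid - water) molecular formulas
RESIDUE_FORMULA: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

RESIDUE_MASS: dict[str, float] = {
    aa: formula_mass(f) for aa, f in RESIDUE_FORMULA.items()
}

WATER = formula_mass("H2O")

# BS3 cross-linker chemistry
BS3_BRIDGE = formula_mass("C8H10O2")  # both arms reacted
BS3_DEADEND_WATER = formula_mass("C8H12O3")  # one arm hydrolysed
BS3_DEADEND_AMMONIA = formula_mass("C8H13NO2")  # one arm aminolysed

# modification deltas
CARBAMIDOMETHYL = formula_mass("C2H3NO")  # fixed on Cys
OXIDATION = formula_mass("O")  # variable on Met
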