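"""Element data: standard atomic weights (amu) and covalent radii (Å).

Covalent radii follow the widely used single-bond values of Cordero et
al. (2008); masses are IUPAC standard atomic weights.  Only elements
common in organic/biomolecular systems are tabulated — extend the dicts
if you need more.
"""

from __future__ import annotations

ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "He": 4.002602,
    "Li": 6.94,
    "Be": 9.0121831,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Al": 26.9815385,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.0983,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Br": 79.904,
    "I": 126.90447,
}

COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31,
    "He": 0.28,
    "Li": 1.28,
    "Be": 0.96,
    "B": 0.84,
    "C": 0.76,   # sp3 value
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Ne": 0.58,
    "Na": 1.66,
    "Mg": 1.41,
    "Al": 1.21,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Ar": 1.06,
    "K": 2.03,
    "Ca": 1.76,
    "Fe": 1.32,
    "Zn": 1.22,
    "Br": 1.20,
    "I": 1.39,
}


def normalize_symbol(sym: str) -> str:
    """Case-normalize an element symbol ('cl' -> 'Cl')."""
    s = sym.strip()
    if not s:
        raise ValueError("empty element symbol")
    return s[0].upper() + s[1:].lower()


def mass_of(sym: str) -> float:
    try:
        return ATOMIC_MASS[normalize_symbol(sym)]
    except KeyError:
        raise KeyError(f"unknown element symbol: {sym!r}") from None


def covalent_radius_of(sym: str) -> float:
    try:
        return COVALENT_RADIUS[normalize_symbol(sym)]
    except KeyError:
        raise KeyError(f"unknown element symbol: {sym!r}") from None
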