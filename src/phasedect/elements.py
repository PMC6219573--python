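"""Bundled atomic numbers and standard atomic weights (H through I plus spares).

Small, hard-coded table so the package works without network access.
Weights are CIAAW 2021 conventional values.
"""

from __future__ import annotations

ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Ti": 22, "Cr": 24,
    "Mn": 25, "Fe": 26, "Cu": 29, "Zn": 30, "Br": 35, "I": 53,
}

ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Cu": 63.546,
    "Zn": 65.38, "Br": 79.904, "I": 126.904,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the bundled table."""


def atomic_number(symbol: str) -> int:
    try:
        return ATOMIC_NUMBER[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element symbol {symbol!r} is not in the bundled Z/A table"
        ) from None


def atomic_weight(symbol: str) -> float:
    try:
        return ATOMIC_WEIGHT[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element symbol {symbol!r} is not in the bundled Z/A table"
        ) from None
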