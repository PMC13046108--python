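"""Elemental constants used throughout the package.

Atomic numbers, standard atomic weights (g/mol) and mean excitation
energies I (eV, ICRU-style values) for every element that appears in the
packaged ink and skin compositions.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    A: float  # g/mol
    I_eV: float  # mean excitation energy


ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("H", 1, 1.008, 19.2),
        Element("C", 6, 12.011, 78.0),
        Element("N", 7, 14.007, 82.0),
        Element("O", 8, 15.999, 95.0),
        Element("Na", 11, 22.990, 149.0),
        Element("Al", 13, 26.982, 166.0),
        Element("P", 15, 30.974, 173.0),
        Element("S", 16, 32.06, 180.0),
        Element("K", 19, 39.098, 190.0),
        Element("Ca", 20, 40.078, 191.0),
        Element("V", 23, 50.942, 245.0),
        Element("Cr", 24, 51.996, 257.0),
        Element("Fe", 26, 55.845, 286.0),
        Element("Co", 27, 58.933, 297.0),
        Element("Ni", 28, 58.693, 311.0),
        Element("Cu", 29, 63.546, 322.0),
        Element("Zn", 30, 65.38, 330.0),
        Element("Cd", 48, 112.41, 469.0),
        Element("Ba", 56, 137.33, 491.0),
        Element("Hg", 80, 200.59, 800.0),
        Element("Pb", 82, 207.2, 823.0),
    ]
}

# Stoichiometric mass ratios for the pigment compounds named in the study.
MOLAR_MASS = {
    "Fe2O3": 2 * ELEMENTS["Fe"].A + 3 * ELEMENTS["O"].A,
    "Al(OH)3": ELEMENTS["Al"].A + 3 * (ELEMENTS["O"].A + ELEMENTS["H"].A),
}

WATER_FRACTIONS = {
    "H": 2 * ELEMENTS["H"].A / (2 * ELEMENTS["H"].A + ELEMENTS["O"].A),
    "O": ELEMENTS["O"].A / (2 * ELEMENTS["H"].A + ELEMENTS["O"].A),
}
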