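"""Residue-level constants: alphabet, elemental formulas, hydropathy scales,
ionization constants and the default physicochemical grouping.

Elemental formulas are those of the free amino acids; a residue inside a chain
is the free acid minus one water, and the whole peptide is the residue sum
plus one water. Masses are derived from standard average atomic weights so
formulas and masses cannot drift apart.
"""

from __future__ import annotations

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# (C, H, N, O, S) of the free amino acid
FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0),
    "C": (3, 7, 1, 2, 1),
    "D": (4, 7, 1, 4, 0),
    "E": (5, 9, 1, 4, 0),
    "F": (9, 11, 1, 2, 0),
    "G": (2, 5, 1, 2, 0),
    "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "K": (6, 14, 2, 2, 0),
    "L": (6, 13, 1, 2, 0),
    "M": (5, 11, 1, 2, 1),
    "N": (4, 8, 2, 3, 0),
    "P": (5, 9, 1, 2, 0),
    "Q": (5, 10, 2, 3, 0),
    "R": (6, 14, 4, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "T": (4, 9, 1, 3, 0),
    "V": (5, 11, 1, 2, 0),
    "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0),
}

ELEMENTS = "CHNOS"
ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
WATER_FORMULA = (0, 2, 0, 1, 0)
WATER_MASS = 2 * ATOMIC_WEIGHTS["H"] + ATOMIC_WEIGHTS["O"]


def formula_mass(formula: tuple[int, int, int, int, int]) -> float:
    return sum(n * ATOMIC_WEIGHTS[e] for n, e in zip(formula, ELEMENTS))


# Average mass of each free amino acid, from its formula.
RESIDUE_FREE_MASS = {aa: formula_mass(f) for aa, f in FORMULAS.items()}

# Kyte & Doolittle hydropathy (the GRAVY scale).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Eisenberg consensus hydrophobicity.
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

SCALES = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG,
}

# Default pKa set (a widely used sequence-analysis default).
DEFAULT_PKA_NTERM = 8.6
DEFAULT_PKA_CTERM = 3.6
DEFAULT_PKA_SIDE_CHAINS = {
    # basic
    "K": 10.8, "R": 12.5, "H": 6.5,
    # acidic
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
BASIC_RESIDUES = frozenset("KRH")
ACIDIC_RESIDUES = frozenset("DECY")

# Default 5-way physicochemical partition used by the k-spaced group-pair
# block.  Short codes appear in feature names; the alias map collapses the
# two hydrophobic groups to "H" for report display.
DEFAULT_GROUPS: dict[str, str] = {
    "ALI": "GAVLMI",   # aliphatic
    "ARO": "FYW",      # aromatic
    "PC": "KRH",       # positively charged
    "NC": "DE",        # negatively charged
    "PNC": "STCPNQ",   # polar non-charged
}
GROUP_ALIASES = {"ALI": "H", "ARO": "H", "PC": "PC", "NC": "NC", "PNC": "PNC"}
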