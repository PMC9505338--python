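"""Reference tables for sequence descriptors.

All tables are keyed by the 20 standard one-letter amino-acid codes. The
residue-level physicochemical constants (hydropathy, hydrophilicity,
side-chain mass, Grantham distance/polarity, atomic composition, N-end-rule
half-lives) are the classical published values used throughout the protein
descriptor literature.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Symbols that mark ambiguous or non-standard residues in database sequences.
AMBIGUOUS_AA = set("BJOUXZ*-")

#: Reserved 21st symbol for the windowed-dipeptide alphabet (placeholder for
#: any non-standard residue admitted under a permissive policy; validated
#: sequences never contain it, so its counts are structurally zero).
OTHER_SYMBOL = "X"

# ---------------------------------------------------------------------------
# Six physicochemical amino-acid groups (counts + frequencies block)
# ---------------------------------------------------------------------------

#: Fixed group order: hydrophobic, negatively charged, positively charged,
#: conformational, polar, other.
AA_GROUPS_6: dict[str, str] = {
    "hydrophobic": "VILFMWYC",
    "negative": "DE",
    "positive": "RKH",
    "conformational": "GP",
    "polar": "NQS",
    "other": "AT",
}

# ---------------------------------------------------------------------------
# CTD: the seven classical three-class property partitions
# ---------------------------------------------------------------------------

#: property -> (class1, class2, class3); each triple partitions the 20 letters.
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASCTPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

# ---------------------------------------------------------------------------
# Scales used by PAAC/APAAC, autocorrelation defaults and GRAVY
# ---------------------------------------------------------------------------

#: Kyte–Doolittle hydropathy.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Hopp–Woods hydrophilicity.
HOPP_WOODS: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

#: Side-chain mass (Da), the third member of the classical PAAC triplet.
SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

#: Grantham (1974) residue polarity.
GRANTHAM_POLARITY: dict[str, float] = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

#: Default autocorrelation scale set (name -> per-residue scale).
DEFAULT_AUTOCORR_SCALES: dict[str, dict[str, float]] = {
    "kd_hydropathy": KYTE_DOOLITTLE,
    "hw_hydrophilicity": HOPP_WOODS,
    "side_chain_mass": SIDE_CHAIN_MASS,
    "polarity": GRANTHAM_POLARITY,
}

# ---------------------------------------------------------------------------
# Grantham chemical distance matrix
# ---------------------------------------------------------------------------

# Upper triangle of the published Grantham (1974) distance table, listed as
# (a, b): distance with three-letter order collapsed to one-letter codes.
_GRANTHAM_UPPER: dict[tuple[str, str], float] = {
    ("S", "R"): 110, ("S", "L"): 145, ("S", "P"): 74, ("S", "T"): 58,
    ("S", "A"): 99, ("S", "V"): 124, ("S", "G"): 56, ("S", "I"): 142,
    ("S", "F"): 155, ("S", "Y"): 144, ("S", "C"): 112, ("S", "H"): 89,
    ("S", "Q"): 68, ("S", "N"): 46, ("S", "K"): 121, ("S", "D"): 65,
    ("S", "E"): 80, ("S", "M"): 135, ("S", "W"): 177,
    ("R", "L"): 102, ("R", "P"): 103, ("R", "T"): 71, ("R", "A"): 112,
    ("R", "V"): 96, ("R", "G"): 125, ("R", "I"): 97, ("R", "F"): 97,
    ("R", "Y"): 77, ("R", "C"): 180, ("R", "H"): 29, ("R", "Q"): 43,
    ("R", "N"): 86, ("R", "K"): 26, ("R", "D"): 96, ("R", "E"): 54,
    ("R", "M"): 91, ("R", "W"): 101,
    ("L", "P"): 98, ("L", "T"): 92, ("L", "A"): 96, ("L", "V"): 32,
    ("L", "G"): 138, ("L", "I"): 5, ("L", "F"): 22, ("L", "Y"): 36,
    ("L", "C"): 198, ("L", "H"): 99, ("L", "Q"): 113, ("L", "N"): 153,
    ("L", "K"): 107, ("L", "D"): 172, ("L", "E"): 138, ("L", "M"): 15,
    ("L", "W"): 61,
    ("P", "T"): 38, ("P", "A"): 27, ("P", "V"): 68, ("P", "G"): 42,
    ("P", "I"): 95, ("P", "F"): 114, ("P", "Y"): 110, ("P", "C"): 169,
    ("P", "H"): 77, ("P", "Q"): 76, ("P", "N"): 91, ("P", "K"): 103,
    ("P", "D"): 108, ("P", "E"): 93, ("P", "M"): 87, ("P", "W"): 147,
    ("T", "A"): 58, ("T", "V"): 69, ("T", "G"): 59, ("T", "I"): 89,
    ("T", "F"): 103, ("T", "Y"): 92, ("T", "C"): 149, ("T", "H"): 47,
    ("T", "Q"): 42, ("T", "N"): 65, ("T", "K"): 78, ("T", "D"): 85,
    ("T", "E"): 65, ("T", "M"): 81, ("T", "W"): 128,
    ("A", "V"): 64, ("A", "G"): 60, ("A", "I"): 94, ("A", "F"): 113,
    ("A", "Y"): 112, ("A", "C"): 195, ("A", "H"): 86, ("A", "Q"): 91,
    ("A", "N"): 111, ("A", "K"): 106, ("A", "D"): 126, ("A", "E"): 107,
    ("A", "M"): 84, ("A", "W"): 148,
    ("V", "G"): 109, ("V", "I"): 29, ("V", "F"): 50, ("V", "Y"): 55,
    ("V", "C"): 192, ("V", "H"): 84, ("V", "Q"): 96, ("V", "N"): 133,
    ("V", "K"): 97, ("V", "D"): 152, ("V", "E"): 121, ("V", "M"): 21,
    ("V", "W"): 88,
    ("G", "I"): 135, ("G", "F"): 153, ("G", "Y"): 147, ("G", "C"): 159,
    ("G", "H"): 98, ("G", "Q"): 87, ("G", "N"): 80, ("G", "K"): 127,
    ("G", "D"): 94, ("G", "E"): 98, ("G", "M"): 127, ("G", "W"): 184,
    ("I", "F"): 21, ("I", "Y"): 33, ("I", "C"): 198, ("I", "H"): 94,
    ("I", "Q"): 109, ("I", "N"): 149, ("I", "K"): 102, ("I", "D"): 168,
    ("I", "E"): 134, ("I", "M"): 10, ("I", "W"): 61,
    ("F", "Y"): 22, ("F", "C"): 205, ("F", "H"): 100, ("F", "Q"): 116,
    ("F", "N"): 158, ("F", "K"): 102, ("F", "D"): 177, ("F", "E"): 140,
    ("F", "M"): 28, ("F", "W"): 40,
    ("Y", "C"): 194, ("Y", "H"): 83, ("Y", "Q"): 99, ("Y", "N"): 143,
    ("Y", "K"): 85, ("Y", "D"): 160, ("Y", "E"): 122, ("Y", "M"): 36,
    ("Y", "W"): 37,
    ("C", "H"): 174, ("C", "Q"): 154, ("C", "N"): 139, ("C", "K"): 202,
    ("C", "D"): 154, ("C", "E"): 170, ("C", "M"): 196, ("C", "W"): 215,
    ("H", "Q"): 24, ("H", "N"): 68, ("H", "K"): 32, ("H", "D"): 81,
    ("H", "E"): 40, ("H", "M"): 87, ("H", "W"): 115,
    ("Q", "N"): 46, ("Q", "K"): 53, ("Q", "D"): 61, ("Q", "E"): 29,
    ("Q", "M"): 101, ("Q", "W"): 130,
    ("N", "K"): 94, ("N", "D"): 23, ("N", "E"): 42, ("N", "M"): 142,
    ("N", "W"): 174,
    ("K", "D"): 101, ("K", "E"): 56, ("K", "M"): 95, ("K", "W"): 110,
    ("D", "E"): 45, ("D", "M"): 160, ("D", "W"): 181,
    ("E", "M"): 126, ("E", "W"): 152,
    ("M", "W"): 67,
}


def grantham_matrix() -> np.ndarray:
    """Symmetric 20x20 Grantham distance matrix in ``STANDARD_AA`` order."""
    idx = {a: i for i, a in enumerate(STANDARD_AA)}
    m = np.zeros((20, 20))
    for (a, b), d in _GRANTHAM_UPPER.items():
        m[idx[a], idx[b]] = d
        m[idx[b], idx[a]] = d
    return m

# ---------------------------------------------------------------------------
# Conjoint-triad seven-class grouping
# ---------------------------------------------------------------------------

#: Classes ordered 1..7: small/aliphatic dipoles through cysteine.
TRIAD_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# ---------------------------------------------------------------------------
# Physicochemical block constants
# ---------------------------------------------------------------------------

#: Per-residue atom counts (C, H, N, O, S) for residues in a peptide chain
#: (free amino acid minus one water); one water is added per chain.
ATOMIC_COMPOSITION: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 5, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "C": (3, 5, 1, 1, 1),
    "E": (5, 7, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "G": (2, 3, 1, 1, 0),
    "H": (6, 7, 3, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "L": (6, 11, 1, 1, 0),
    "K": (6, 12, 2, 1, 0),
    "M": (5, 9, 1, 1, 1),
    "F": (9, 9, 1, 1, 0),
    "P": (5, 7, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "T": (4, 7, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "V": (5, 9, 1, 1, 0),
}

#: N-end-rule half-lives in hours keyed by N-terminal residue, per host:
#: (mammalian reticulocyte, yeast, E. coli). Open intervals (">20 h", ">10 h")
#: are encoded at their lower bound; the unknown E. coli value for Pro is
#: encoded in the ">10 h" class.
HALF_LIFE_HOURS: dict[str, tuple[float, float, float]] = {
    "A": (4.4, 20.0, 10.0),
    "R": (1.0, 1 / 30, 1 / 30),
    "N": (1.4, 0.05, 10.0),
    "D": (1.1, 0.05, 10.0),
    "C": (1.2, 20.0, 10.0),
    "Q": (0.8, 1 / 6, 10.0),
    "E": (1.0, 0.5, 10.0),
    "G": (30.0, 20.0, 10.0),
    "H": (3.5, 1 / 6, 10.0),
    "I": (20.0, 0.5, 10.0),
    "L": (5.5, 0.05, 1 / 30),
    "K": (1.3, 0.05, 1 / 30),
    "M": (30.0, 20.0, 10.0),
    "F": (1.1, 0.05, 1 / 30),
    "P": (20.0, 20.0, 10.0),
    "S": (1.9, 20.0, 10.0),
    "T": (7.2, 20.0, 10.0),
    "W": (2.8, 0.05, 1 / 30),
    "Y": (2.8, 1 / 6, 1 / 30),
    "V": (100.0, 20.0, 10.0),
}

#: Gill–von Hippel molar extinction increments at 280 nm (M^-1 cm^-1).
EXTINCTION_TRP = 5500.0
EXTINCTION_TYR = 1490.0
EXTINCTION_CYSTINE = 125.0

#: Mass of one water molecule (average isotopic, Da).
WATER_MASS = 18.0153


def standardize_scale(scale: dict[str, float]) -> dict[str, float]:
    """Standardize a 20-residue scale to mean 0, population SD 1."""
    vals = np.array([scale[a] for a in STANDARD_AA], dtype=float)
    mu = vals.mean()
    sd = vals.std()  # population SD over the 20 residues
    if sd == 0:
        raise ValueError("scale has zero variance over the 20 amino acids")
    return {a: (scale[a] - mu) / sd for a in STANDARD_AA}
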