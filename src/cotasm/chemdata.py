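"""Reference chemistry tables used across the pipeline.

All values are published standards shipped as data so that every
classification made by the pipeline is reproducible from this file alone.
"""

from __future__ import annotations

# Heavy-atom van der Waals radii (Å); hydrogens are ignored throughout.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

#: Default radius for elements missing from the table (Å).
DEFAULT_RADIUS = 1.70

#: Apolar amino acids used for apolar interface area and surface composition.
APOLAR_AA = frozenset("AFGILVMPY")

#: Charged amino acids (His treated as polar).
CHARGED_AA = frozenset("DEKR")

POSITIVE_AA = frozenset("RK")
NEGATIVE_AA = frozenset("DE")

#: Theoretical maximum accessible surface area per residue (Å²),
#: Tien et al. 2013 (theoretical column), used to normalise rASA.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Nonstandard residue names mapped to canonical one-letter codes.
NONSTANDARD_MAP: dict[str, str] = {
    "MSE": "M",  # selenomethionine
    "SEC": "C", "CSE": "C",  # selenocysteine
    "CSO": "C", "CSS": "C", "CME": "C", "OCS": "C",  # modified Cys
    "SEP": "S", "TPO": "T", "PTR": "Y",  # phosphorylated
    "MLY": "K", "M3L": "K", "KCX": "K",  # modified Lys
    "HYP": "P",  # hydroxyproline
    "PCA": "E",  # pyroglutamate
    "FME": "M",  # formylmethionine
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Side-chain and terminal pKa values (EMBOSS set) for titration curves.
PKA_SIDECHAIN: dict[str, float] = {
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5,
}
PKA_NTERM = 8.6
PKA_CTERM = 3.6
#: Residues whose protonated form is positively charged.
BASIC_AA = frozenset("HKR")
#: Residues whose deprotonated form is negatively charged.
ACIDIC_AA = frozenset("DECY")


def residue_class(aa: str) -> str:
    """Chemical class of a residue: ``charged``, ``apolar`` or ``polar``."""
    if aa in CHARGED_AA:
        return "charged"
    if aa in APOLAR_AA:
        return "apolar"
    return "polar"
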