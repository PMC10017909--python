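"""Physical constants and residue-level property tables.

Units used throughout the package: lengths in Å, volumes in Å³, times in
ns, pressures in bar, temperatures in K, energies in kcal/mol.
"""

from __future__ import annotations

#: Boltzmann constant, exact SI value (J/K).
K_B = 1.380649e-23

#: Volume conversion, 1 Å³ in m³.
A3_TO_M3 = 1e-30

#: Pressure conversion, 1 bar in Pa.
BAR_TO_PA = 1e5

#: Default van der Waals radii (Å) by element symbol (Bondi-style values).
#: Overridable wherever a radius table is accepted.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "NA": 2.27,
    "CL": 1.75,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
}

#: Elements whose atoms count as polar for SASA partitioning.
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

#: The 20 standard amino acids, one-letter codes, alphabetical.
AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_AA1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA1_TO_AA3: dict[str, str] = {v: k for k, v in AA3_TO_AA1.items()}

#: Kyte–Doolittle hydropathy index.
HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Mean residue volumes (Å³), Zamyatnin-style.
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Helix propensity (kcal/mol, Pace & Scholtz scale; 0 = most helix-favoring).
HELIX_PROPENSITY: dict[str, float] = {
    "A": 0.0, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
    "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
    "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
    "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.0, "P": 3.16,
}
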