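"""Shared amino-acid and physico-chemical constant tables.

The class order used everywhere a 20-vector or an (n, 20) probability matrix
appears is the fixed alphabetical one-letter order ``AA_ORDER``.  Persisted
artefacts (HDF5 datasets, model sidecars, CSV reports) record this order so
that indices are never ambiguous.
"""

from __future__ import annotations

#: Fixed alphabetical one-letter class order for all 20-way outputs.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Sentinel label for residues outside the 20 canonical classes.
UNKNOWN_LABEL = 255

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is folded into methionine; other modified
    # residues are skipped at parse time
    "MSE": "M",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

#: Zimmerman (1968) polarity scale, AAindex entry ZIMJ680103.
#: Residues with a value below 20 are treated as non-polar (-1),
#: the rest as polar (+1); only D, E, H, K, R clear the threshold.
ZIMMERMAN_POLARITY = {
    "A": 0.00, "R": 52.00, "N": 3.38, "D": 49.70, "C": 1.48,
    "Q": 3.53, "E": 49.90, "G": 0.00, "H": 51.60, "I": 0.13,
    "L": 0.13, "K": 49.50, "M": 1.43, "F": 0.35, "P": 1.58,
    "S": 1.67, "T": 1.66, "W": 2.10, "Y": 1.61, "V": 0.13,
}

ZIMMERMAN_POLAR_THRESHOLD = 20.0

#: Side-chain formal charge at neutral pH used for the charge input channel.
#: Histidine is grouped with the basic residues (+1).
RESIDUE_CHARGE = {
    **{aa: 0 for aa in AA_ORDER},
    "D": -1, "E": -1,
    "K": +1, "R": +1, "H": +1,
}

#: EMBOSS pKa set used for Henderson-Hasselbalch net-charge and pI.
EMBOSS_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
EMBOSS_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

#: Van der Waals radii (Angstrom) by element, used for Gaussian atom rendering.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52}

#: Ideal backbone internal coordinates (Angstrom / degrees) used by the
#: synthetic backbone builder and the virtual C-beta construction.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_CA_CB = 1.522
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
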