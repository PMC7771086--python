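"""Shared chemical tables: residue codes, radii, reference ASA maxima,
side-chain torsion definitions, rotamer defaults and amino-acid SMILES."""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA3 = frozenset(THREE_TO_ONE)
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: default residue-level capping groups removed before pocket analysis
CAP_RESIDUE_NAMES = frozenset({"ACE", "ACY", "NME", "NH2", "DAM", "CH2"})

#: pocket labels N->C along the substrate; scissile bond between S1 and S1'
POCKET_ORDER = ("S4", "S3", "S2", "S1", "S1'", "S2'", "S3'", "S4'")
#: matching substrate position labels
POSITION_ORDER = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")

BACKBONE_HEAVY = frozenset({"N", "CA", "C", "O", "OXT"})
BACKBONE_H = frozenset({"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"})
BACKBONE_NAMES = BACKBONE_HEAVY | BACKBONE_H

#: van der Waals radii (A), used both for ASA and Lennard-Jones minima
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

#: Lennard-Jones well depths (model-internal units)
LJ_EPSILON = {
    "H": 0.016, "C": 0.11, "N": 0.17, "O": 0.21, "S": 0.25, "P": 0.20,
    "SE": 0.25, "F": 0.15, "CL": 0.20, "BR": 0.20, "I": 0.20,
}

#: theoretical maximum residue ASA (A^2) in an extended Gly-X-Gly context
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: side-chain torsion (chi) atom quadruplets, standard definitions
CHI_ATOMS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

#: most-common rotamer chi values (deg); compact single-conformer table
ROTAMER_CHI = {
    "ARG": (-65.0, 180.0, 180.0, 180.0),
    "ASN": (-65.0, -20.0),
    "ASP": (-65.0, -15.0),
    "CYS": (-65.0,),
    "GLN": (-65.0, 180.0, 0.0),
    "GLU": (-65.0, 180.0, 0.0),
    "HIS": (-65.0, -75.0),
    "ILE": (-65.0, 170.0),
    "LEU": (-65.0, 175.0),
    "LYS": (-65.0, 180.0, 180.0, 180.0),
    "MET": (-65.0, 180.0, 75.0),
    "PHE": (-65.0, 90.0),
    "SER": (64.0,),
    "THR": (62.0,),
    "TRP": (-65.0, 95.0),
    "TYR": (-65.0, 90.0),
    "VAL": (175.0,),
}

#: neutral-form amino-acid SMILES for fingerprint similarity
AA_SMILES = {
    "A": "CC(N)C(=O)O",
    "R": "NC(CCCNC(N)=N)C(=O)O",
    "N": "NC(CC(N)=O)C(=O)O",
    "D": "NC(CC(O)=O)C(=O)O",
    "C": "NC(CS)C(=O)O",
    "E": "NC(CCC(O)=O)C(=O)O",
    "Q": "NC(CCC(N)=O)C(=O)O",
    "G": "NCC(=O)O",
    "H": "NC(Cc1c[nH]cn1)C(=O)O",
    "I": "CCC(C)C(N)C(=O)O",
    "L": "CC(C)CC(N)C(=O)O",
    "K": "NCCCCC(N)C(=O)O",
    "M": "CSCCC(N)C(=O)O",
    "F": "NC(Cc1ccccc1)C(=O)O",
    "P": "OC(=O)C1CCCN1",
    "S": "NC(CO)C(=O)O",
    "T": "CC(O)C(N)C(=O)O",
    "W": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "Y": "NC(Cc1ccc(O)cc1)C(=O)O",
    "V": "CC(C)C(N)C(=O)O",
}

# ideal backbone internal coordinates (A / deg) for peptide extension
BOND_C_N = 1.329
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_O = 1.231
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0
#: extended-strand backbone torsions used as the default conformer
PHI_EXTENDED = -139.0
PSI_EXTENDED = 135.0
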