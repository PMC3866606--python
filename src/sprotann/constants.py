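"""Shared constant tables: ideal covalent geometry, amino-acid alphabets and
composition tables, interface propensities, and metal coordination chemistry.

All coordinates and distances are in Angstrom, all angles in degrees unless
stated otherwise. These values are the single authoritative source of
synthetic geometry for the whole package.
"""

from __future__ import annotations

# --- backbone covalent geometry (ideal values) -------------------------------
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
BOND_N_H = 1.0

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5

# Improper dihedral C-N-CA-CB fixing L-chirality of the side chain stub.
DIHEDRAL_C_N_CA_CB = 122.6

# Canonical torsions used by the synthetic fold builder.
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 120.0)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
EXTENDED_AA_SET = frozenset(AMINO_ACIDS + "X")

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

# Background amino-acid frequencies (vertebrate-like composition) used by the
# sequence generators and the quasi-chemical potential.
BACKGROUND_FREQUENCIES = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.029, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

# Interface propensity table for the binding-residue score: log-odds-like
# values, positive for residue types over-represented in protein-protein
# interfaces. Shipped as a fixed fixture.
INTERFACE_PROPENSITY = {
    "W": 0.83, "F": 0.62, "M": 0.60, "I": 0.44, "Y": 0.42,
    "L": 0.40, "C": 0.30, "V": 0.27, "R": 0.27, "H": 0.20,
    "A": 0.00, "T": 0.00, "G": -0.08, "N": -0.10, "Q": -0.10,
    "P": -0.10, "S": -0.12, "D": -0.20, "E": -0.22, "K": -0.36,
}

# Residue types over-represented in interfaces; the dimer generator draws
# interface residues from this set so the propensity table carries signal.
INTERFACE_ENRICHED_AA = "WFMILYV"

METAL_TYPES = ("Ca", "Zn", "Mg", "Ni", "Fe", "Cu", "Mn", "Co")

# Chemically apt coordinating residue types per metal. Backbone-oxygen
# coordination for the alkaline-earth metals is handled by the caller.
METAL_CHEMISTRY = {
    "Zn": frozenset("CHDE"),
    "Ca": frozenset("DENQST"),
    "Mg": frozenset("DENQST"),
    "Fe": frozenset("HCMY"),
    "Cu": frozenset("HCM"),
    "Mn": frozenset("HDE"),
    "Ni": frozenset("HDE"),
    "Co": frozenset("HDE"),
}

# Apt mutation targets used when the holo-template generator plants a metal
# site (subset of METAL_CHEMISTRY biased to the classic coordinators).
METAL_SITE_RESIDUES = {
    "Zn": "CCHH",
    "Ca": "DDEN",
    "Mg": "DDEN",
    "Fe": "HHC",
    "Cu": "HHC",
    "Mn": "HDE",
    "Ni": "HDE",
    "Co": "HDE",
}

# Beta-turn torsions calibrated so a strand-turn-strand chain built from
# ideal geometry closes into a hydrogen-bonded antiparallel hairpin.
BETA_TURN_TORSIONS = ((15.0, -105.0), (-90.0, 10.0))

# Mixture of bound metal types used by the benchmark generator (calcium,
# zinc and magnesium dominate proteome-wide surveys).
METAL_TYPE_MIXTURE = {
    "Ca": 0.30, "Zn": 0.29, "Mg": 0.24, "Ni": 0.06,
    "Fe": 0.04, "Cu": 0.03, "Mn": 0.02, "Co": 0.02,
}

# Polar-biased composition for solvent-exposed protein surfaces; the dimer
# generator draws monomer sequences from it before re-typing interface
# residues hydrophobic, mirroring the polar-surface/apolar-interface contrast
# of real complexes.
SURFACE_POLAR_FREQUENCIES = {
    "A": 0.08, "C": 0.01, "D": 0.09, "E": 0.10, "F": 0.01,
    "G": 0.08, "H": 0.03, "I": 0.02, "K": 0.10, "L": 0.03,
    "M": 0.01, "N": 0.07, "P": 0.05, "Q": 0.06, "R": 0.07,
    "S": 0.09, "T": 0.07, "V": 0.03, "W": 0.003, "Y": 0.02,
}
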