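"""Bundled physical-chemistry tables used across the package.

All length units are Angstrom (Å); hydropathy values are dimensionless.
"""

from __future__ import annotations

import math

# Kyte-Doolittle hydropathy scale (one-letter code -> hydropathy).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Three-letter <-> one-letter residue codes (standard amino acids only).
AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3: dict[str, str] = {v: k for k, v in AA_3TO1.items()}

# Van der Waals radii by element (Å). Elements outside the table get
# VDW_DEFAULT; predictor models are heavy-atom only, so C/N/O/S cover
# essentially everything.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_DEFAULT: float = 1.70

# Residue van der Waals volumes (Å³), Chothia-style packing volumes.
RESIDUE_VOLUMES: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Contact envelope added to the volume-equivalent side-chain sphere so the
# single-sphere side-chain proxy used by the mutation scan has a realistic
# collision surface (Glu -> 3.1 Å, matching an all-atom Glu side chain).
_SPHERE_ENVELOPE = 0.45


def _side_chain_sphere_radius(aa: str) -> float:
    """Volume-equivalent radius of a residue's side chain plus envelope."""
    if aa == "G":
        return 1.0  # a single hydrogen; fixed small sphere
    v_sc = RESIDUE_VOLUMES[aa] - RESIDUE_VOLUMES["G"]
    return (3.0 * v_sc / (4.0 * math.pi)) ** (1.0 / 3.0) + _SPHERE_ENVELOPE


# Single-sphere side-chain radii (Å) used for point-mutation modelling.
SIDE_CHAIN_SPHERE_RADII: dict[str, float] = {
    aa: round(_side_chain_sphere_radius(aa), 2) for aa in RESIDUE_VOLUMES
}

# Ideal Cβ geometry used when constructing a side-chain direction for
# glycine (tetrahedral Cα).
CA_CB_DISTANCE = 1.53  # Å, not used directly for sphere placement
SIDE_CHAIN_SPHERE_OFFSET = 2.4  # Å from Cα along the Cα->Cβ direction

WATER_MASS = 18.0153  # Da, released per peptide bond / added once per chain


def vdw_radius(element: str) -> float:
    """vdW radius (Å) for an element symbol; unknown elements get the default."""
    return VDW_RADII.get(element.strip().upper(), VDW_DEFAULT)
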