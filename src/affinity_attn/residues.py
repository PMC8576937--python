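"""Covalent connectivity templates for the 20 standard amino-acid residues.

Bond orders follow the PDB chemical component dictionary in localized
(Kekulized) form: ring bonds of HIS/PHE/TYR/TRP alternate single/double rather
than being flagged aromatic, the backbone carbonyl is a double bond, and
side-chain amide C-N bonds (ASN/GLN) carry the amide kind. The inter-residue
peptide C-N bond is typed amide as well. Only bonds whose two atoms are both
present in a structure are instantiated, so truncated residues are handled
gracefully.
"""

from __future__ import annotations

from .chem import BondKind

S, D, AM = BondKind.SINGLE, BondKind.DOUBLE, BondKind.AMIDE

#: Backbone bonds common to all residues (OXT covers C-terminal carboxylates).
BACKBONE_BONDS: list[tuple[str, str, BondKind]] = [
    ("N", "CA", S),
    ("CA", "C", S),
    ("C", "O", D),
    ("C", "OXT", S),
    ("CA", "CB", S),
]

SIDECHAIN_BONDS: dict[str, list[tuple[str, str, BondKind]]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("CB", "OG", S)],
    "CYS": [("CB", "SG", S)],
    "THR": [("CB", "OG1", S), ("CB", "CG2", S)],
    "VAL": [("CB", "CG1", S), ("CB", "CG2", S)],
    "LEU": [("CB", "CG", S), ("CG", "CD1", S), ("CG", "CD2", S)],
    "ILE": [("CB", "CG1", S), ("CB", "CG2", S), ("CG1", "CD1", S)],
    "MET": [("CB", "CG", S), ("CG", "SD", S), ("SD", "CE", S)],
    "PRO": [("CB", "CG", S), ("CG", "CD", S), ("CD", "N", S)],
    "PHE": [
        ("CB", "CG", S),
        ("CG", "CD1", D),
        ("CD1", "CE1", S),
        ("CE1", "CZ", D),
        ("CZ", "CE2", S),
        ("CE2", "CD2", D),
        ("CD2", "CG", S),
    ],
    "TYR": [
        ("CB", "CG", S),
        ("CG", "CD1", D),
        ("CD1", "CE1", S),
        ("CE1", "CZ", D),
        ("CZ", "CE2", S),
        ("CE2", "CD2", D),
        ("CD2", "CG", S),
        ("CZ", "OH", S),
    ],
    "TRP": [
        ("CB", "CG", S),
        ("CG", "CD1", D),
        ("CD1", "NE1", S),
        ("NE1", "CE2", S),
        ("CE2", "CD2", D),
        ("CD2", "CG", S),
        ("CD2", "CE3", S),
        ("CE3", "CZ3", D),
        ("CZ3", "CH2", S),
        ("CH2", "CZ2", D),
        ("CZ2", "CE2", S),
    ],
    "HIS": [
        ("CB", "CG", S),
        ("CG", "ND1", S),
        ("CG", "CD2", D),
        ("ND1", "CE1", D),
        ("CD2", "NE2", S),
        ("CE1", "NE2", S),
    ],
    "ASP": [("CB", "CG", S), ("CG", "OD1", D), ("CG", "OD2", S)],
    "GLU": [("CB", "CG", S), ("CG", "CD", S), ("CD", "OE1", D), ("CD", "OE2", S)],
    "ASN": [("CB", "CG", S), ("CG", "OD1", D), ("CG", "ND2", AM)],
    "GLN": [("CB", "CG", S), ("CG", "CD", S), ("CD", "OE1", D), ("CD", "NE2", AM)],
    "LYS": [("CB", "CG", S), ("CG", "CD", S), ("CD", "CE", S), ("CE", "NZ", S)],
    "ARG": [
        ("CB", "CG", S),
        ("CG", "CD", S),
        ("CD", "NE", S),
        ("NE", "CZ", S),
        ("CZ", "NH1", S),
        ("CZ", "NH2", D),
    ],
}

#: Maximum C(i)-N(i+1) distance (Angstrom) accepted as a peptide bond.
PEPTIDE_BOND_MAX = 1.8

#: Maximum SG-SG distance (Angstrom) accepted as a disulfide bridge.
DISULFIDE_MAX = 2.3


def residue_bonds(resname: str) -> list[tuple[str, str, BondKind]]:
    """All intra-residue heavy-atom bonds for a standard residue name.

    Unknown residue names yield an empty list (their atoms stay unbonded).
    """
    side = SIDECHAIN_BONDS.get(resname.upper())
    if side is None:
        return []
    return BACKBONE_BONDS + side
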