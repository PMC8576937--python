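"""Shared chemical vocabulary: heavy-atom types, bond kinds, van der Waals radii.

The descriptor scheme is restricted to the nine heavy elements commonly
observed in protein-ligand complexes (C, N, O, F, P, S, Cl, Br, I); atoms of
any other element are carried through structures but are invisible to contact,
descriptor and interaction-term computations.
"""

from __future__ import annotations

from enum import Enum

#: Fixed order of the nine heavy-atom types. Positions double as type indices.
HEAVY_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")

_HEAVY_INDEX = {e: i for i, e in enumerate(HEAVY_ELEMENTS)}


def heavy_atom_index(element: str) -> int | None:
    """Position of ``element`` in the nine-type order (C=0 ... I=8), else None."""
    return _HEAVY_INDEX.get(normalize_element(element))


def normalize_element(element: str) -> str:
    """Canonical capitalization for an element symbol ('CL' -> 'Cl')."""
    s = element.strip()
    if not s:
        raise ValueError("empty element symbol")
    return s[0].upper() + s[1:].lower()


class BondKind(str, Enum):
    """The five bond kinds distinguished by the descriptor encoding."""

    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AMIDE = "amide"
    AROMATIC = "aromatic"

    @property
    def code(self) -> str:
        return _BOND_CODES[self]

    @property
    def rank(self) -> int:
        return _BOND_RANK[self]

    @property
    def order(self) -> float:
        """Nominal bond order used for implicit-hydrogen (valence) bookkeeping."""
        return _BOND_ORDER[self]


_BOND_CODES = {
    BondKind.SINGLE: "s",
    BondKind.DOUBLE: "d",
    BondKind.TRIPLE: "t",
    BondKind.AMIDE: "am",
    BondKind.AROMATIC: "ar",
}

_BOND_RANK = {
    BondKind.SINGLE: 0,
    BondKind.DOUBLE: 1,
    BondKind.TRIPLE: 2,
    BondKind.AMIDE: 3,
    BondKind.AROMATIC: 4,
}

_BOND_ORDER = {
    BondKind.SINGLE: 1.0,
    BondKind.DOUBLE: 2.0,
    BondKind.TRIPLE: 3.0,
    BondKind.AMIDE: 1.0,
    BondKind.AROMATIC: 1.5,
}

#: MOL2 TRIPOS bond codes <-> BondKind. 'un' (unknown) and 'du' (dummy) are
#: conservatively read as single bonds; 'nc' (not connected) is skipped.
MOL2_BOND_CODES = {
    "1": BondKind.SINGLE,
    "2": BondKind.DOUBLE,
    "3": BondKind.TRIPLE,
    "am": BondKind.AMIDE,
    "ar": BondKind.AROMATIC,
    "un": BondKind.SINGLE,
    "du": BondKind.SINGLE,
}

#: Atomic van der Waals radii (Angstrom) for surface-distance computation,
#: AutoDock-style values for the nine heavy-atom types.
VDW_RADII: dict[str, float] = {
    "C": 1.9,
    "N": 1.8,
    "O": 1.7,
    "F": 1.5,
    "P": 2.1,
    "S": 2.0,
    "Cl": 1.8,
    "Br": 2.0,
    "I": 2.2,
}

#: Default valence used to infer implicit hydrogens on hydrogen-stripped
#: structures (donor typing only).
DEFAULT_VALENCE: dict[str, int] = {"N": 3, "O": 2, "C": 4, "S": 2, "P": 3}

#: Pairwise contact cutoff (Angstrom) defining descriptor contacts.
DESCRIPTOR_CUTOFF = 12.0

#: Pairwise interaction cutoff (Angstrom) for the Vina-style terms.
VINA_CUTOFF = 8.0
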