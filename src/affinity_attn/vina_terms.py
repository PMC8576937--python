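"""Vina-style intermolecular interaction terms.

Six auxiliary features per complex: two attractive Gaussians and a repulsion
evaluated on the van-der-Waals surface distance, a hydrophobic contact ramp, a
hydrogen-bond ramp, and the ligand's active rotatable-bond count. Pairwise
terms are summed over all intermolecular heavy-atom pairs within an 8 A
interaction cutoff; the hydrophobic term only over carbon-carbon pairs where
both carbons carry no hetero substituent, the hydrogen-bond term only over
donor/acceptor pairs. Atom typing works on hydrogen-stripped structures:
donor hydrogens are inferred from free valence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chem import (
    DEFAULT_VALENCE,
    VDW_RADII,
    VINA_CUTOFF,
    BondKind,
    heavy_atom_index,
)
from .complex_io import Atom, ComplexStructure


@dataclass(frozen=True)
class VinaTerms:
    """The six Vina-style features of one complex."""

    gauss1: float
    gauss2: float
    repulsion: float
    hydrophobic: float
    hbond: float
    n_rot: int

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.gauss1, self.gauss2, self.repulsion, self.hydrophobic, self.hbond, float(self.n_rot))


PAIR_TERM_KINDS = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")


def surface_distance(atom_i: Atom, atom_j: Atom, radii: dict[str, float] = VDW_RADII) -> float:
    """Surface-to-surface distance d = r_ij - R_i - R_j (Angstrom)."""
    for atom in (atom_i, atom_j):
        if atom.element not in radii:
            raise KeyError(f"no van der Waals radius for element {atom.element!r}")
    r = math.dist(atom_i.coords, atom_j.coords)
    return r - radii[atom_i.element] - radii[atom_j.element]


def pair_term(kind: str, d: float) -> float:
    """Evaluate one distance-dependent pairwise term at surface distance d."""
    if kind == "gauss1":
        return math.exp(-((d / 0.5) ** 2))
    if kind == "gauss2":
        return math.exp(-(((d - 3.0) / 2.0) ** 2))
    if kind == "repulsion":
        return d * d if d < 0 else 0.0
    if kind == "hydrophobic":
        return _ramp(d, 0.5, 1.5)
    if kind == "hbond":
        return _ramp(d, -0.7, 0.0)
    raise ValueError(f"unknown pair term {kind!r}")


def _ramp(d: float, lo: float, hi: float) -> float:
    """Linear ramp: 1 below ``lo``, 0 above ``hi``."""
    if d <= lo:
        return 1.0
    if d >= hi:
        return 0.0
    return (hi - d) / (hi - lo)


def is_hydrophobic(structure: ComplexStructure, atom: int) -> bool:
    """Carbon bonded only to carbon (hydrogens are implicit and allowed)."""
    a = structure.atoms[atom]
    if a.element != "C":
        return False
    return all(structure.atoms[j].element == "C" for _, j in structure.adjacency()[atom])


def implicit_hydrogens(structure: ComplexStructure, atom: int) -> int:
    """Free valence of an atom after its explicit heavy bonds, floored at 0."""
    a = structure.atoms[atom]
    valence = DEFAULT_VALENCE.get(a.element)
    if valence is None:
        return 0
    used = sum(kind.order for kind, _ in structure.adjacency()[atom])
    return max(0, int(valence - math.ceil(used - 1e-9)))


def is_donor(structure: ComplexStructure, atom: int) -> bool:
    """Nitrogen with at least one (implicit) hydrogen."""
    return structure.atoms[atom].element == "N" and implicit_hydrogens(structure, atom) >= 1


def is_acceptor(structure: ComplexStructure, atom: int) -> bool:
    return structure.atoms[atom].element in ("N", "O")


def compute_vina_features(
    structure: ComplexStructure, cutoff: float = VINA_CUTOFF
) -> VinaTerms:
    """Sum the five pairwise terms over intermolecular pairs within cutoff."""
    lig = [a for a in structure.ligand_atoms() if heavy_atom_index(a.element) is not None]
    prot = [a for a in structure.protein_atoms() if heavy_atom_index(a.element) is not None]
    g1 = g2 = rep = phob = hb = 0.0
    for la in lig:
        for pa in prot:
            if math.dist(la.coords, pa.coords) > cutoff:
                continue
            d = surface_distance(la, pa)
            g1 += pair_term("gauss1", d)
            g2 += pair_term("gauss2", d)
            rep += pair_term("repulsion", d)
            if is_hydrophobic(structure, la.index) and is_hydrophobic(structure, pa.index):
                phob += pair_term("hydrophobic", d)
            if (is_donor(structure, la.index) and is_acceptor(structure, pa.index)) or (
                is_donor(structure, pa.index) and is_acceptor(structure, la.index)
            ):
                hb += pair_term("hbond", d)
    return VinaTerms(g1, g2, rep, phob, hb, rotatable_bond_count(structure))


def rotatable_bond_count(structure: ComplexStructure) -> int:
    """Active rotatable bonds of the ligand.

    Counts ligand single bonds that are acyclic (bridges of the ligand bond
    graph), non-terminal (both ends have >= 2 heavy neighbors) and not amide.
    """
    lig_idx = {a.index for a in structure.ligand_atoms()}
    lig_bonds = [b for b in structure.bonds if b.a in lig_idx]
    degree: dict[int, int] = {i: 0 for i in lig_idx}
    for b in lig_bonds:
        degree[b.a] += 1
        degree[b.b] += 1
    count = 0
    for b in lig_bonds:
        if b.kind != BondKind.SINGLE:
            continue
        if degree[b.a] < 2 or degree[b.b] < 2:
            continue
        if _in_ring(b, lig_bonds):
            continue
        count += 1
    return count


def _in_ring(bond, bonds) -> bool:
    """True if the endpoints stay connected when the bond is removed."""
    adj: dict[int, set[int]] = {}
    for b in bonds:
        if b is bond:
            continue
        adj.setdefault(b.a, set()).add(b.b)
        adj.setdefault(b.b, set()).add(b.a)
    stack, seen = [bond.a], {bond.a}
    while stack:
        node = stack.pop()
        if node == bond.b:
            return True
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False
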