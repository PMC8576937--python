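"""Loading and preprocessing of protein-ligand complexes.

A complex is represented as a flat heavy-atom graph (:class:`ComplexStructure`)
holding both binding partners: protein atoms parsed from PDB with bonds
perceived from residue templates, and ligand atoms parsed from MOL2/SDF with
bonds taken from the file. Preprocessing removes hydrogens, water molecules
and any HETATM group other than the named ligand (cofactors), mirroring the
standard refined-set protocol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio.PDB import PDBParser

from .chem import (
    MOL2_BOND_CODES,
    BondKind,
    HEAVY_ELEMENTS,
    heavy_atom_index,
    normalize_element,
)
from .residues import DISULFIDE_MAX, PEPTIDE_BOND_MAX, residue_bonds

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ComplexParseError(ValueError):
    """A structure file could not be parsed; message names file (and line)."""


class BondsRequiredError(ComplexParseError):
    """Ligand file carries no bond records, which the descriptors require."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a complex.

    ``chain_id``/``residue`` are set for protein atoms only; ``name`` is the
    PDB/MOL2 atom name, kept so structures can be round-tripped to disk.
    """

    index: int
    element: str
    role: str  # "protein" | "ligand"
    coords: tuple[float, float, float]
    chain_id: str | None = None
    residue: tuple[str, int] | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"bad atom role {self.role!r}")
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.index}")


@dataclass(frozen=True)
class Bond:
    """Covalent bond between two atoms of the same molecule."""

    a: int
    b: int
    kind: BondKind

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-bond")

    def other(self, idx: int) -> int:
        return self.b if idx == self.a else self.a


@dataclass
class ComplexStructure:
    """Heavy-atom graph of one protein-ligand complex."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    _adjacency: dict[int, list[tuple[BondKind, int]]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise ValueError(f"atom index {atom.index} at position {i}")
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond endpoint out of range: {bond}")
            if self.atoms[bond.a].role != self.atoms[bond.b].role:
                raise ValueError("covalent protein-ligand bonds are not allowed")

    # -- views ------------------------------------------------------------
    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.role == "ligand"]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.role == "protein"]

    def adjacency(self) -> dict[int, list[tuple[BondKind, int]]]:
        if self._adjacency is None:
            adj: dict[int, list[tuple[BondKind, int]]] = {
                a.index: [] for a in self.atoms
            }
            for bond in self.bonds:
                adj[bond.a].append((bond.kind, bond.b))
                adj[bond.b].append((bond.kind, bond.a))
            self._adjacency = adj
        return self._adjacency

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexStructure):
            return NotImplemented
        return (
            self.id == other.id
            and self.atoms == other.atoms
            and sorted(self.bonds, key=_bond_key) == sorted(other.bonds, key=_bond_key)
        )


def _bond_key(b: Bond) -> tuple[int, int, str]:
    lo, hi = min(b.a, b.b), max(b.a, b.b)
    return (lo, hi, b.kind.value)


def neighbors(structure: ComplexStructure, atom: int) -> list[tuple[BondKind, Atom]]:
    """Bonded heavy-atom neighbors of ``atom`` with their bond kinds.

    Neighbors whose element falls outside the nine descriptor atom types are
    omitted. Order is deterministic (by neighbor atom index).
    """
    adj = structure.adjacency()
    if atom not in adj:
        raise KeyError(f"no atom with index {atom}")
    out = []
    for kind, j in sorted(adj[atom], key=lambda kj: kj[1]):
        other = structure.atoms[j]
        if heavy_atom_index(other.element) is not None:
            out.append((kind, other))
    return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_complex(protein_path: str | Path, ligand_path: str | Path, id: str) -> ComplexStructure:
    """Parse and preprocess a complex from a protein PDB and a ligand MOL2/SDF.

    Waters (HOH/WAT), hydrogens and cofactor HETATM groups are removed; ligand
    bond kinds come from the file, protein bonds from residue templates plus
    peptide and disulfide perception.
    """
    protein_path, ligand_path = Path(protein_path), Path(ligand_path)
    p_atoms, p_bonds = _load_protein_pdb(protein_path)
    suffix = ligand_path.suffix.lower()
    if suffix == ".mol2":
        l_atoms, l_bonds = read_mol2(ligand_path)
    elif suffix in (".sdf", ".mol", ".sd"):
        l_atoms, l_bonds = read_sdf(ligand_path)
    else:
        raise ComplexParseError(f"{ligand_path}: unsupported ligand format {suffix!r}")

    bad = {a[1] for a in l_atoms if heavy_atom_index(a[1]) is None}
    if bad:
        raise ComplexParseError(
            f"{ligand_path}: ligand contains uncommon elements {sorted(bad)}; "
            f"supported heavy atoms are {list(HEAVY_ELEMENTS)}"
        )

    atoms: list[Atom] = []
    for name, element, xyz, chain, res in p_atoms:
        atoms.append(
            Atom(len(atoms), element, "protein", xyz, chain_id=chain, residue=res, name=name)
        )
    offset = len(atoms)
    for name, element, xyz in l_atoms:
        atoms.append(Atom(len(atoms), element, "ligand", xyz, name=name))
    bonds = [Bond(a, b, k) for a, b, k in p_bonds]
    bonds += [Bond(a + offset, b + offset, k) for a, b, k in l_bonds]
    return ComplexStructure(id, atoms, bonds)


def _load_protein_pdb(path: Path):
    """Heavy protein atoms + template-perceived bonds from a PDB file."""
    parser = PDBParser(QUIET=True)
    try:
        model = next(parser.get_structure("prot", str(path)).get_models())
    except StopIteration:
        raise ComplexParseError(f"{path}: no model records") from None
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ComplexParseError(f"{path}: {exc}") from exc

    atoms: list[tuple[str, str, tuple[float, float, float], str, tuple[str, int]]] = []
    bonds: list[tuple[int, int, BondKind]] = []
    sg_indices: list[int] = []

    for chain in model:
        prev_c: int | None = None
        for residue in chain:
            hetfield, resseq, _ = residue.id
            resname = residue.get_resname().strip()
            if resname in WATER_NAMES or hetfield.strip():
                prev_c = None
                continue  # waters and cofactors are removed
            local: dict[str, int] = {}
            for atom in residue:
                if atom.is_disordered():
                    atom = atom.disordered_get()
                element = normalize_element(atom.element or atom.get_name()[0])
                if element in ("H", "D"):
                    continue
                name = atom.get_name().strip()
                if name not in local:  # first altloc wins
                    local[name] = len(atoms)
                    # PDB coordinates carry three decimals; round so reloads
                    # of written fixtures compare exactly
                    xyz = tuple(round(float(c), 3) for c in atom.coord)
                    atoms.append((name, element, xyz, chain.id, (resname, int(resseq))))
            for a_name, b_name, kind in residue_bonds(resname):
                if a_name in local and b_name in local:
                    bonds.append((local[a_name], local[b_name], kind))
            if resname == "CYS" and "SG" in local:
                sg_indices.append(local["SG"])
            if prev_c is not None and "N" in local:
                if _dist(atoms[prev_c][2], atoms[local["N"]][2]) <= PEPTIDE_BOND_MAX:
                    bonds.append((prev_c, local["N"], BondKind.AMIDE))
            prev_c = local.get("C")

    for i, a in enumerate(sg_indices):
        for b in sg_indices[i + 1:]:
            if _dist(atoms[a][2], atoms[b][2]) <= DISULFIDE_MAX:
                bonds.append((a, b, BondKind.SINGLE))
    return atoms, bonds


def _dist(p, q) -> float:
    return math.dist(p, q)


def read_mol2(path: str | Path):
    """TRIPOS MOL2 reader that preserves the five bond kind codes.

    Returns ``(atoms, bonds)`` with atoms as (name, element, xyz) and bonds as
    0-based heavy-atom index triples. Hydrogens (and their bonds) are dropped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    section = None
    raw_atoms: dict[int, tuple[str, str, tuple[float, float, float]]] = {}
    raw_bonds: list[tuple[int, int, BondKind]] = []
    saw_bond_section = False
    for ln, line in enumerate(lines, 1):
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[9:].upper()
            if section == "BOND":
                saw_bond_section = True
            continue
        if not stripped or stripped.startswith("#"):
            continue
        if section == "ATOM":
            parts = stripped.split()
            if len(parts) < 6:
                raise ComplexParseError(f"{path}:{ln}: malformed ATOM record")
            try:
                aid = int(parts[0])
                xyz = (float(parts[2]), float(parts[3]), float(parts[4]))
            except ValueError as exc:
                raise ComplexParseError(f"{path}:{ln}: {exc}") from exc
            element = normalize_element(parts[5].split(".")[0])
            raw_atoms[aid] = (parts[1], element, xyz)
        elif section == "BOND":
            parts = stripped.split()
            if len(parts) < 4:
                raise ComplexParseError(f"{path}:{ln}: malformed BOND record")
            code = parts[3].lower()
            if code == "nc":
                continue
            kind = MOL2_BOND_CODES.get(code)
            if kind is None:
                raise ComplexParseError(f"{path}:{ln}: unknown bond type {code!r}")
            raw_bonds.append((int(parts[1]), int(parts[2]), kind))
    if not raw_atoms:
        raise ComplexParseError(f"{path}: no ATOM section")
    if not saw_bond_section:
        raise BondsRequiredError(f"{path}: bonds required (no @<TRIPOS>BOND section)")

    keep = {aid: rec for aid, rec in raw_atoms.items() if rec[1] not in ("H", "D")}
    remap = {aid: i for i, aid in enumerate(sorted(keep))}
    atoms = [keep[aid] for aid in sorted(keep)]
    bonds = [
        (remap[a], remap[b], kind)
        for a, b, kind in raw_bonds
        if a in remap and b in remap
    ]
    return atoms, bonds


_RDKIT_BOND_KINDS = {
    "SINGLE": BondKind.SINGLE,
    "DOUBLE": BondKind.DOUBLE,
    "TRIPLE": BondKind.TRIPLE,
    "AROMATIC": BondKind.AROMATIC,
}


def read_sdf(path: str | Path):
    """Ligand atoms/bonds from an SDF/MOL file via RDKit (no sanitization)."""
    from rdkit import Chem

    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ComplexParseError(f"{path}: RDKit could not parse any molecule")
    if mol.GetNumBonds() == 0 and mol.GetNumAtoms() > 1:
        raise BondsRequiredError(f"{path}: bonds required (empty bond block)")
    conf = mol.GetConformer()
    atoms = []
    remap: dict[int, int] = {}
    for rd_atom in mol.GetAtoms():
        element = normalize_element(rd_atom.GetSymbol())
        if element in ("H", "D"):
            continue
        pos = conf.GetAtomPosition(rd_atom.GetIdx())
        remap[rd_atom.GetIdx()] = len(atoms)
        atoms.append((f"{element}{len(atoms)+1}", element, (pos.x, pos.y, pos.z)))
    bonds = []
    for rd_bond in mol.GetBonds():
        a, b = rd_bond.GetBeginAtomIdx(), rd_bond.GetEndAtomIdx()
        if a not in remap or b not in remap:
            continue
        kind = _RDKIT_BOND_KINDS.get(str(rd_bond.GetBondType()))
        if kind is None:
            kind = BondKind.SINGLE
        bonds.append((remap[a], remap[b], kind))
    return atoms, bonds


# ---------------------------------------------------------------------------
# writing (fixtures, round-trips)
# ---------------------------------------------------------------------------


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write the protein part of a structure as minimal PDB ATOM records."""
    lines = []
    serial = 0
    for atom in structure.protein_atoms():
        serial += 1
        name = atom.name or atom.element
        resname, resseq = atom.residue or ("UNK", 1)
        pad_name = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {serial:5d} {pad_name:<4s} {resname:<3s} {atom.chain_id or 'A'}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_MOL2_CODES = {
    BondKind.SINGLE: "1",
    BondKind.DOUBLE: "2",
    BondKind.TRIPLE: "3",
    BondKind.AMIDE: "am",
    BondKind.AROMATIC: "ar",
}


def write_mol2(structure: ComplexStructure, path: str | Path) -> None:
    """Write the ligand part of a structure as a TRIPOS MOL2 file."""
    lig = structure.ligand_atoms()
    remap = {a.index: i + 1 for i, a in enumerate(lig)}
    bonds = [b for b in structure.bonds if b.a in remap]
    lines = [
        "@<TRIPOS>MOLECULE",
        structure.id,
        f"{len(lig)} {len(bonds)} 0 0 0",
        "SMALL",
        "NO_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, atom in enumerate(lig, 1):
        x, y, z = atom.coords
        name = atom.name or f"{atom.element}{i}"
        lines.append(f"{i:>4d} {name:<6s} {x:>10.4f} {y:>10.4f} {z:>10.4f} {atom.element}")
    lines.append("@<TRIPOS>BOND")
    for i, bond in enumerate(bonds, 1):
        lines.append(f"{i:>4d} {remap[bond.a]:>4d} {remap[bond.b]:>4d} {_MOL2_CODES[bond.kind]}")
    Path(path).write_text("\n".join(lines) + "\n")


def structure_to_dict(structure: ComplexStructure) -> dict:
    return {
        "id": structure.id,
        "atoms": [
            {
                "index": a.index,
                "element": a.element,
                "role": a.role,
                "coords": list(a.coords),
                "chain_id": a.chain_id,
                "residue": list(a.residue) if a.residue else None,
                "name": a.name,
            }
            for a in structure.atoms
        ],
        "bonds": [[b.a, b.b, b.kind.value] for b in structure.bonds],
    }


def structure_from_dict(data: dict) -> ComplexStructure:
    atoms = [
        Atom(
            d["index"],
            d["element"],
            d["role"],
            tuple(d["coords"]),
            chain_id=d.get("chain_id"),
            residue=tuple(d["residue"]) if d.get("residue") else None,
            name=d.get("name"),
        )
        for d in data["atoms"]
    ]
    bonds = [Bond(a, b, BondKind(k)) for a, b, k in data["bonds"]]
    return ComplexStructure(data["id"], atoms, bonds)


def write_json(structure: ComplexStructure, path: str | Path) -> None:
    Path(path).write_text(json.dumps(structure_to_dict(structure), indent=1))


def read_json(path: str | Path) -> ComplexStructure:
    return structure_from_dict(json.loads(Path(path).read_text()))


def translated(structure: ComplexStructure, offset: tuple[float, float, float]) -> ComplexStructure:
    """Copy of the structure rigidly translated by ``offset``."""
    atoms = [
        replace(a, coords=(a.coords[0] + offset[0], a.coords[1] + offset[1], a.coords[2] + offset[2]))
        for a in structure.atoms
    ]
    return ComplexStructure(structure.id, atoms, list(structure.bonds))
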