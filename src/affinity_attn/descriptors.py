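"""Intermolecular contact descriptors.

Every (ligand heavy atom, protein heavy atom) pair within 12 A forms a
contact. Each contact is extended by the one-bond neighborhoods of both atoms
and encoded as an order-invariant canonical string; a complex is then the
frequency vector of those strings over a fixed vocabulary learned from
training data. Only the nine common heavy-atom types (C, N, O, F, P, S, Cl,
Br, I) participate.

Canonical serialization: ``L:<elem>[<b>:<e>,...]|P:<elem>[<b>:<e>,...]`` with
neighbor lists sorted by (element rank in the nine-type order, bond rank
single<double<triple<amide<aromatic) and bond codes s,d,t,am,ar. E.g. the
contact "ligand hydroxyl O near a backbone carbonyl O" serializes as
``L:O[s:C]|P:O[d:C]``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .chem import DESCRIPTOR_CUTOFF, BondKind, heavy_atom_index
from .complex_io import ComplexStructure, neighbors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contact:
    """One intermolecular heavy-atom pair within the cutoff."""

    ligand_atom: int
    protein_atom: int
    distance: float


@dataclass(frozen=True)
class Descriptor:
    """Canonical one-step-neighborhood encoding of a contact."""

    ligand_center: str
    protein_center: str
    ligand_neighbors: tuple[tuple[BondKind, str], ...]
    protein_neighbors: tuple[tuple[BondKind, str], ...]

    @property
    def canonical(self) -> str:
        return "|".join(
            (
                _side("L", self.ligand_center, self.ligand_neighbors),
                _side("P", self.protein_center, self.protein_neighbors),
            )
        )


def _neighbor_key(item: tuple[BondKind, str]) -> tuple[int, int]:
    kind, elem = item
    return (heavy_atom_index(elem), kind.rank)


def _side(tag: str, center: str, nbrs: tuple[tuple[BondKind, str], ...]) -> str:
    inner = ",".join(f"{k.code}:{e}" for k, e in sorted(nbrs, key=_neighbor_key))
    return f"{tag}:{center}[{inner}]"


class DescriptorVocabulary:
    """Ordered, duplicate-free list of canonical descriptor strings."""

    def __init__(self, entries: list[str] | tuple[str, ...]):
        self.entries: list[str] = list(entries)
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("vocabulary entries must be unique")
        self.index: dict[str, int] = {s: i for i, s in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, DescriptorVocabulary) and self.entries == other.entries


def find_contacts(
    structure: ComplexStructure, cutoff: float = DESCRIPTOR_CUTOFF
) -> list[Contact]:
    """All intermolecular heavy-atom pairs with Euclidean distance <= cutoff.

    Uses a k-d tree for the neighbor query; ordering is deterministic (ligand
    atom index, then protein atom index).
    """
    lig = [a for a in structure.ligand_atoms() if heavy_atom_index(a.element) is not None]
    prot = [a for a in structure.protein_atoms() if heavy_atom_index(a.element) is not None]
    if cutoff <= 0 or not lig or not prot:
        return []
    lig_xyz = np.array([a.coords for a in lig])
    prot_xyz = np.array([a.coords for a in prot])
    tree = cKDTree(prot_xyz)
    contacts: list[Contact] = []
    for li, hits in enumerate(tree.query_ball_point(lig_xyz, cutoff)):
        for pj in sorted(hits):
            d = float(np.linalg.norm(lig_xyz[li] - prot_xyz[pj]))
            contacts.append(Contact(lig[li].index, prot[pj].index, d))
    return contacts


def build_descriptor(contact: Contact, structure: ComplexStructure) -> Descriptor:
    """Extend a contact by the one-bond neighborhoods of its two atoms."""
    lig_atom = structure.atoms[contact.ligand_atom]
    prot_atom = structure.atoms[contact.protein_atom]
    lig_nbrs = tuple((k, a.element) for k, a in neighbors(structure, contact.ligand_atom))
    prot_nbrs = tuple((k, a.element) for k, a in neighbors(structure, contact.protein_atom))
    return Descriptor(lig_atom.element, prot_atom.element, lig_nbrs, prot_nbrs)


def extract_descriptor_counts(
    structure: ComplexStructure, cutoff: float = DESCRIPTOR_CUTOFF
) -> Counter[str]:
    """Multiset of canonical descriptor strings, one instance per contact."""
    counts: Counter[str] = Counter()
    for contact in find_contacts(structure, cutoff):
        counts[build_descriptor(contact, structure).canonical] += 1
    return counts


def build_vocabulary(
    training: list[ComplexStructure], cutoff: float = DESCRIPTOR_CUTOFF
) -> DescriptorVocabulary:
    """Union of all canonical strings in a training set, lexicographic order."""
    if not training:
        raise ValueError("cannot build a vocabulary from an empty training set")
    seen: set[str] = set()
    for structure in training:
        seen.update(extract_descriptor_counts(structure, cutoff))
    return DescriptorVocabulary(sorted(seen))


def vectorize(
    structure: ComplexStructure,
    vocab: DescriptorVocabulary,
    cutoff: float = DESCRIPTOR_CUTOFF,
) -> np.ndarray:
    """Frequency vector of the vocabulary's descriptors in one complex.

    Descriptors observed in the complex but absent from the vocabulary are
    dropped (their number is logged at DEBUG level).
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty")
    counts = extract_descriptor_counts(structure, cutoff)
    vec = np.zeros(len(vocab), dtype=np.int64)
    dropped = 0
    for key, mult in counts.items():
        pos = vocab.index.get(key)
        if pos is None:
            dropped += mult
        else:
            vec[pos] = mult
    if dropped:
        logger.debug("%s: %d contact(s) mapped to out-of-vocabulary descriptors", structure.id, dropped)
    return vec


def select_top_descriptors(
    X: np.ndarray,
    y: np.ndarray,
    u: int,
    seed: int,
    vocab: DescriptorVocabulary,
    n_estimators: int = 500,
) -> DescriptorVocabulary:
    """Rank descriptors by random-forest importance and keep the top ``u``.

    A random-forest regressor is fit on the count matrix and affinities, and
    features are ordered by decreasing impurity-based importance (ties broken
    by original vocabulary position). Reproducible given ``seed``.
    """
    from sklearn.ensemble import RandomForestRegressor

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != len(vocab):
        raise ValueError("X width does not match vocabulary size")
    if u > X.shape[1]:
        raise ValueError(f"u={u} exceeds the {X.shape[1]} available descriptors")
    if X.shape[0] < 2:
        raise ValueError("need at least two training complexes")
    forest = RandomForestRegressor(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    order = np.lexsort((np.arange(len(vocab)), -forest.feature_importances_))
    return DescriptorVocabulary([vocab.entries[i] for i in order[:u]])
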