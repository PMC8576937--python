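"""Shared fixtures: the worked-example complex and random synthetic complexes."""

from __future__ import annotations

import math

import pytest

from affinity_attn.complex_io import Atom, Bond, ComplexStructure
from affinity_attn.synthetic import generate_complex, make_two_contact_fixture


@pytest.fixture
def two_contact():
    return make_two_contact_fixture()


@pytest.fixture
def random_complexes():
    """A batch of small random pocket+ligand complexes with varied density."""
    return [
        generate_complex(seed, n_ligand=6, n_pocket=14, contact_density=0.2 + 0.2 * (seed % 4))
        for seed in range(12)
    ]


def brute_force_contacts(structure, cutoff):
    """All-pairs reference for contact detection (independent of the k-d tree)."""
    from affinity_attn.chem import heavy_atom_index

    pairs = []
    for la in structure.ligand_atoms():
        if heavy_atom_index(la.element) is None:
            continue
        for pa in structure.protein_atoms():
            if heavy_atom_index(pa.element) is None:
                continue
            if math.dist(la.coords, pa.coords) <= cutoff:
                pairs.append((la.index, pa.index))
    return pairs


def merge_structures(a: ComplexStructure, b: ComplexStructure, new_id="merged") -> ComplexStructure:
    """Concatenate two complexes into one (atom indices of b shifted)."""
    offset = len(a.atoms)
    atoms = list(a.atoms)
    for atom in b.atoms:
        atoms.append(
            Atom(
                atom.index + offset,
                atom.element,
                atom.role,
                atom.coords,
                chain_id=atom.chain_id,
                residue=atom.residue,
                name=atom.name,
            )
        )
    bonds = list(a.bonds) + [Bond(x.a + offset, x.b + offset, x.kind) for x in b.bonds]
    return ComplexStructure(new_id, atoms, bonds)
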