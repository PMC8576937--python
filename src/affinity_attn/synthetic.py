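"""Synthetic complexes and datasets with known ground truth.

Provides (a) a deterministic two-contact worked-example complex whose
descriptor set is known exactly, (b) seeded random "pocket + ligand"
complexes with controllable contact density for property tests, and (c)
tabular descriptor/Vina datasets with a plantable linear affinity signal for
parameter-recovery studies. Generated geometry is deliberately minimal: tree
bond topologies and shell placements, not force-field-valid conformers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import HEAVY_ELEMENTS, BondKind
from .complex_io import (
    Atom,
    Bond,
    ComplexStructure,
    write_json,
    write_mol2,
    write_pdb,
)
from .vina_terms import VinaTerms

#: The two canonical descriptors of the worked-example fixture.
TWO_CONTACT_DESCRIPTORS = ("L:O[s:C]|P:O[d:C]", "L:O[s:C]|P:C[s:C,d:C]")


def make_two_contact_fixture() -> ComplexStructure:
    """Deterministic complex with exactly two contacts at the 12 A cutoff.

    Two spatially separated fragment pairs are placed collinearly 11.5 A
    apart with neighbor atoms pointing away, so precisely two intermolecular
    heavy-atom pairs fall inside 12 A (every other cross-distance exceeds
    12.6 A):

    * a ligand hydroxyl-like O (single-bonded C neighbor) facing a backbone
      carbonyl O (double-bonded C neighbor) -> ``L:O[s:C]|P:O[d:C]``;
    * a second ligand O facing an aromatic-ring carbon carrying one single
      and one double C-C bond (PHE CD2) -> ``L:O[s:C]|P:C[s:C,d:C]``.

    The protein fragments are truncated GLY and PHE residues, so writing the
    structure to PDB and reloading it reproduces the same bonds through
    residue-template perception.
    """
    atoms = [
        Atom(0, "C", "protein", (12.73, 0.0, 0.0), "A", ("GLY", 1), "C"),
        Atom(1, "O", "protein", (11.5, 0.0, 0.0), "A", ("GLY", 1), "O"),
        Atom(2, "C", "protein", (12.8, 100.75, 0.0), "A", ("PHE", 5), "CG"),
        Atom(3, "C", "protein", (11.5, 100.0, 0.0), "A", ("PHE", 5), "CD2"),
        Atom(4, "C", "protein", (12.64, 99.2, 0.0), "A", ("PHE", 5), "CE2"),
        Atom(5, "O", "ligand", (0.0, 0.0, 0.0), name="O1"),
        Atom(6, "C", "ligand", (-1.43, 0.0, 0.0), name="C2"),
        Atom(7, "O", "ligand", (0.0, 100.0, 0.0), name="O3"),
        Atom(8, "C", "ligand", (-1.43, 100.0, 0.0), name="C4"),
    ]
    bonds = [
        Bond(0, 1, BondKind.DOUBLE),
        Bond(4, 3, BondKind.DOUBLE),
        Bond(3, 2, BondKind.SINGLE),
        Bond(5, 6, BondKind.SINGLE),
        Bond(7, 8, BondKind.SINGLE),
    ]
    return ComplexStructure("two-contact", atoms, bonds)


def write_two_contact_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the worked-example fixture as PDB + MOL2 + expected-descriptor JSON."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = make_two_contact_fixture()
    paths = {
        "protein": outdir / "two_contact_protein.pdb",
        "ligand": outdir / "two_contact_ligand.mol2",
        "structure": outdir / "two_contact_structure.json",
        "expected": outdir / "two_contact_expected.json",
    }
    write_pdb(structure, paths["protein"])
    write_mol2(structure, paths["ligand"])
    write_json(structure, paths["structure"])
    paths["expected"].write_text(
        json.dumps({"descriptors": {d: 1 for d in TWO_CONTACT_DESCRIPTORS}, "n_contacts": 2}, indent=1)
    )
    return paths


_ELEMENT_WEIGHTS = np.array([0.55, 0.14, 0.14, 0.03, 0.02, 0.05, 0.04, 0.02, 0.01])
_BOND_CHOICES = [
    BondKind.SINGLE,
    BondKind.DOUBLE,
    BondKind.TRIPLE,
    BondKind.AMIDE,
    BondKind.AROMATIC,
]
_BOND_WEIGHTS = np.array([0.6, 0.15, 0.05, 0.1, 0.1])


def _random_fragment(rng: np.random.Generator, n: int, role: str, index0: int):
    """Random tree-bonded fragment with coordinates from a jittered walk."""
    coords = np.zeros((n, 3))
    parents = []
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        step = rng.normal(size=3)
        step *= 1.5 / np.linalg.norm(step)
        coords[i] = coords[parent] + step
        parents.append(parent)
    elements = rng.choice(HEAVY_ELEMENTS, size=n, p=_ELEMENT_WEIGHTS)
    atoms = []
    for i in range(n):
        kwargs = {"chain_id": "A", "residue": ("UNK", 1)} if role == "protein" else {}
        atoms.append(
            Atom(index0 + i, str(elements[i]), role, tuple(coords[i]), **kwargs)
        )
    kinds = rng.choice(len(_BOND_CHOICES), size=max(n - 1, 0), p=_BOND_WEIGHTS)
    bonds = [
        Bond(index0 + parent, index0 + i + 1, _BOND_CHOICES[k])
        for i, (parent, k) in enumerate(zip(parents, kinds))
    ]
    return atoms, bonds


def generate_complex(
    seed: int, n_ligand: int = 12, n_pocket: int = 30, contact_density: float = 0.7
) -> ComplexStructure:
    """Random pocket + ligand complex; contact count grows with density.

    ``contact_density`` in [0, 1]: 0 places the ligand with every cross
    distance above the 12 A descriptor cutoff (zero contacts); 1 docks it
    against the pocket surface.
    """
    if n_ligand < 1 or n_pocket < 1:
        raise ValueError("fragment sizes must be >= 1")
    if not 0.0 <= contact_density <= 1.0:
        raise ValueError("contact_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pocket_atoms, pocket_bonds = _random_fragment(rng, n_pocket, "protein", 0)
    lig_atoms, lig_bonds = _random_fragment(rng, n_ligand, "ligand", n_pocket)
    # separate along +x so the closest surface gap is controlled exactly
    gap = 12.5 - 10.5 * contact_density
    pocket_max_x = max(a.coords[0] for a in pocket_atoms)
    lig_min_x = min(a.coords[0] for a in lig_atoms)
    shift = pocket_max_x + gap - lig_min_x
    lig_atoms = [
        Atom(
            a.index,
            a.element,
            a.role,
            (a.coords[0] + shift, a.coords[1], a.coords[2]),
            name=a.name,
        )
        for a in lig_atoms
    ]
    return ComplexStructure(
        f"synth-{seed}", pocket_atoms + lig_atoms, pocket_bonds + lig_bonds
    )


@dataclass(frozen=True)
class SignalSpec:
    """A plantable linear affinity signal over descriptor counts and gauss1."""

    signal_descriptors: tuple[int, ...]
    weights: tuple[float, ...]  # pK units per descriptor count
    vina_weight: float = 0.05  # pK units per gauss1 unit
    noise_sd: float = 0.3  # pK units

    def __post_init__(self) -> None:
        if len(self.signal_descriptors) != len(self.weights):
            raise ValueError("one weight per signal descriptor")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_signal_spec(vocab_size: int, noise_sd: float = 0.3) -> SignalSpec:
    """Five signal descriptors with mixed-sign effects of |w| in 0.35-0.6 pK."""
    idx = tuple(int(i) for i in np.linspace(3, vocab_size - 5, 5, dtype=int))
    return SignalSpec(idx, (0.6, -0.4, 0.5, 0.35, -0.5), vina_weight=0.05, noise_sd=noise_sd)


def generate_dataset(
    seed: int, n: int, vocab_size: int, spec: SignalSpec
) -> tuple[list[tuple[np.ndarray, VinaTerms, float]], SignalSpec]:
    """Descriptor counts from a Poisson mixture plus a linear affinity signal.

    Counts for descriptor k are Poisson with a per-descriptor rate drawn once
    from Gamma(2, 1.5); the affinity is the planted linear combination of the
    signal counts and the gauss1 term plus Gaussian noise. The rate vector is
    a fixed property of ``vocab_size`` (its own deterministic stream), so
    datasets generated with different seeds are samples from one population
    and can serve as train/validation/test splits.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rates = np.random.default_rng(10_000 + vocab_size).gamma(2.0, 1.5, size=vocab_size)
    counts = rng.poisson(rates, size=(n, vocab_size))
    gauss1 = np.clip(rng.normal(50.0, 10.0, size=n), 0.0, None)
    gauss2 = np.clip(rng.normal(800.0, 120.0, size=n), 0.0, None)
    repulsion = rng.gamma(2.0, 1.0, size=n)
    hydrophobic = rng.gamma(2.0, 5.0, size=n)
    hbond = rng.gamma(2.0, 1.0, size=n)
    n_rot = rng.poisson(5.0, size=n)
    y = (
        counts[:, list(spec.signal_descriptors)] @ np.array(spec.weights)
        + spec.vina_weight * gauss1
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    data = [
        (
            counts[i],
            VinaTerms(
                float(gauss1[i]),
                float(gauss2[i]),
                float(repulsion[i]),
                float(hydrophobic[i]),
                float(hbond[i]),
                int(n_rot[i]),
            ),
            float(y[i]),
        )
        for i in range(n)
    ]
    return data, spec


def rotated_translated(
    structure: ComplexStructure, seed: int
) -> ComplexStructure:
    """Copy of a structure under a random rigid motion (rotation + shift)."""
    from scipy.spatial.transform import Rotation
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    atoms = [
        replace(a, coords=tuple(R @ np.asarray(a.coords) + t)) for a in structure.atoms
    ]
    return ComplexStructure(structure.id, atoms, list(structure.bonds))


def permuted_atoms(structure: ComplexStructure, seed: int) -> ComplexStructure:
    """Copy with atom indices randomly permuted (bond endpoints remapped)."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(structure.atoms))
    remap = {old: int(new) for old, new in zip(range(len(perm)), perm)}
    atoms: list[Atom] = [None] * len(structure.atoms)  # type: ignore[list-item]
    for a in structure.atoms:
        atoms[remap[a.index]] = replace(a, index=remap[a.index])
    bonds = [Bond(remap[b.a], remap[b.b], b.kind) for b in structure.bonds]
    return ComplexStructure(structure.id, atoms, bonds)
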