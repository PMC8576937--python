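"""Regression metrics, model ranking, and structure-similarity utilities.

Metrics follow the CASF scoring-power convention: MAE, RMSE, Pearson and
Spearman correlations, and SD -- the root-mean-square residual of the true
affinities about the least-squares line fitted to the predictions (N-1
denominator). Structure similarity supports redundancy-filtered
generalization splits: protein similarity as the lowest (or highest)
pairwise-chains TM-score via an external TM-align executable, ligand
similarity as the Tanimoto coefficient over 2048-bit Morgan (radius-2)
fingerprints.
"""

from __future__ import annotations

import os
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .complex_io import ComplexStructure

FINGERPRINT_BITS = 2048
FINGERPRINT_RADIUS = 2


@dataclass(frozen=True)
class Metrics:
    mae: float
    rmse: float
    pcc: float
    scc: float
    sd: float

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "rmse": self.rmse, "pcc": self.pcc, "scc": self.scc, "sd": self.sd}


@dataclass(frozen=True)
class SimilarityRecord:
    complex_id: str
    protein_sim: float
    ligand_sim: float


class AlignerNotFoundError(RuntimeError):
    """TM-align is not on PATH (or at the configured location)."""


def regression_metrics(y_true, y_pred) -> Metrics:
    """MAE, RMSE, PCC, SCC and regression SD for predicted affinities."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    n = len(y_true)
    if n < 3:
        raise ValueError("need at least three points")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("correlations undefined for constant input")
    mae = float(np.mean(np.abs(y_true - y_pred)))
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    pcc = float(stats.pearsonr(y_true, y_pred).statistic)
    scc = float(stats.spearmanr(y_true, y_pred).statistic)
    # least-squares line of true on predicted, residual SD with N-1 denominator
    b, a = np.polyfit(y_pred, y_true, 1)
    resid = y_true - (a + b * y_pred)
    sd = float(np.sqrt(np.sum(resid**2) / (n - 1)))
    return Metrics(mae, rmse, pcc, scc, sd)


def average_rank(scores: pd.DataFrame, higher_is_better: bool) -> pd.Series:
    """Mean rank of each model (rows) across datasets (columns).

    Rank 1 is best within each dataset; ties receive the average rank.
    """
    if scores.isna().any().any():
        raise ValueError("score table has missing cells")
    ranks = scores.rank(axis=0, method="average", ascending=not higher_is_better)
    return ranks.mean(axis=1)


# ---------------------------------------------------------------------------
# ligand similarity
# ---------------------------------------------------------------------------


def _ligand_to_rdkit(structure: ComplexStructure):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    from .chem import BondKind

    order = {
        BondKind.SINGLE: Chem.BondType.SINGLE,
        BondKind.DOUBLE: Chem.BondType.DOUBLE,
        BondKind.TRIPLE: Chem.BondType.TRIPLE,
        BondKind.AMIDE: Chem.BondType.SINGLE,
        BondKind.AROMATIC: Chem.BondType.AROMATIC,
    }
    mol = Chem.RWMol()
    remap = {}
    lig = structure.ligand_atoms()
    for atom in lig:
        remap[atom.index] = mol.AddAtom(Chem.Atom(atom.element))
    for bond in structure.bonds:
        if bond.a in remap:
            mol.AddBond(remap[bond.a], remap[bond.b], order[bond.kind])
    conf = Chem.Conformer(len(lig))
    for atom in lig:
        conf.SetAtomPosition(remap[atom.index], Point3D(*atom.coords))
    mol.AddConformer(conf)
    out = mol.GetMol()
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out


def ligand_fingerprint(structure: ComplexStructure) -> set[int]:
    """On-bit set of the ligand's 2048-bit Morgan radius-2 fingerprint."""
    from rdkit.Chem import rdFingerprintGenerator

    mol = _ligand_to_rdkit(structure)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
    )
    fp = gen.GetFingerprint(mol)
    return set(fp.GetOnBits())


def ligand_tanimoto(lig_a: ComplexStructure, lig_b: ComplexStructure) -> float:
    """Tanimoto coefficient |A&B|/|A|B| over fingerprint bit sets (0 if both empty)."""
    a, b = ligand_fingerprint(lig_a), ligand_fingerprint(lig_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# protein similarity (external TM-align)
# ---------------------------------------------------------------------------

_TM_LINE = re.compile(r"TM-score=\s*([0-9.]+)\s*\(.*normalized by length of Chain_([12])", re.I)
_LEN_LINE = re.compile(r"Length of Chain_([12]):\s*(\d+)")


def _tmalign_executable(executable: str | None) -> str:
    exe = executable or os.environ.get("TMALIGN", "TMalign")
    path = shutil.which(exe)
    if path is None:
        raise AlignerNotFoundError(
            f"TM-align executable {exe!r} not found on PATH; install it from "
            "https://zhanggroup.org/TM-align/ or set the TMALIGN environment variable"
        )
    return path


def _run_tmalign(exe: str, chain_a: Path, chain_b: Path) -> float:
    """One TM-align invocation -> TM-score normalized by the shorter chain."""
    result = subprocess.run(
        [exe, str(chain_a), str(chain_b)], capture_output=True, text=True, check=True
    )
    scores: dict[str, float] = {}
    lengths: dict[str, int] = {}
    for line in result.stdout.splitlines():
        m = _TM_LINE.search(line)
        if m:
            scores[m.group(2)] = float(m.group(1))
        m = _LEN_LINE.search(line)
        if m:
            lengths[m.group(1)] = int(m.group(2))
    if not scores:
        raise RuntimeError(f"could not parse TM-score from TM-align output for {chain_a}")
    if len(scores) == 1:
        return next(iter(scores.values()))
    shorter = "1" if lengths.get("1", 0) <= lengths.get("2", 0) else "2"
    return scores.get(shorter, max(scores.values()))


def _split_chains(pdb_path: Path, outdir: Path) -> list[Path]:
    from Bio.PDB import PDBIO, PDBParser, Select

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    io = PDBIO()
    paths = []

    class _One(Select):
        def __init__(self, cid):
            self.cid = cid

        def accept_chain(self, chain):
            return chain.id == self.cid

    for chain in model:
        out = outdir / f"{pdb_path.stem}_{chain.id or 'X'}.pdb"
        io.set_structure(structure)
        io.save(str(out), _One(chain.id))
        paths.append(out)
    return paths


def protein_similarity(
    prot_a: str | Path,
    prot_b: str | Path,
    mode: str = "lowest",
    executable: str | None = None,
) -> float:
    """Lowest/highest pairwise-chains TM-score between two protein PDB files.

    Every chain of ``prot_a`` is aligned against every chain of ``prot_b``
    with the external TM-align tool; failures on individual chain pairs are
    skipped (an error is raised only if every pair fails).
    """
    if mode not in ("lowest", "highest"):
        raise ValueError("mode must be 'lowest' or 'highest'")
    exe = _tmalign_executable(executable)
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        chains_a = _split_chains(Path(prot_a), tmpdir)
        chains_b = _split_chains(Path(prot_b), tmpdir)
        if not chains_a or not chains_b:
            raise ValueError("each protein must have at least one chain")
        scores = []
        for ca in chains_a:
            for cb in chains_b:
                try:
                    scores.append(_run_tmalign(exe, ca, cb))
                except (subprocess.CalledProcessError, RuntimeError):
                    continue
        if not scores:
            raise RuntimeError("TM-align failed on every chain pair")
        return min(scores) if mode == "lowest" else max(scores)


def max_similarity_to_training(
    test_complex,
    training: list,
    kind: str,
    mode: str = "lowest",
    executable: str | None = None,
) -> float:
    """Maximum pairwise similarity of one test complex against a training set."""
    if not training:
        raise ValueError("training list is empty")
    if kind == "ligand":
        return max(ligand_tanimoto(test_complex, t) for t in training)
    if kind == "protein":
        return max(
            protein_similarity(test_complex, t, mode=mode, executable=executable)
            for t in training
        )
    raise ValueError("kind must be 'protein' or 'ligand'")


def generalization_filter(
    test: list[SimilarityRecord],
    protein_threshold: float | None = None,
    ligand_threshold: float | None = None,
) -> list[SimilarityRecord]:
    """Keep test complexes with similarity to training below the threshold.

    Provide ``protein_threshold`` for the protein-structure generalization
    test or ``ligand_threshold`` for the ligand-structure test (or both, in
    which case both conditions must hold).
    """
    if protein_threshold is None and ligand_threshold is None:
        raise ValueError("at least one threshold is required")
    kept = []
    for rec in test:
        if protein_threshold is not None and not rec.protein_sim < protein_threshold:
            continue
        if ligand_threshold is not None and not rec.ligand_sim < ligand_threshold:
            continue
        kept.append(rec)
    return kept
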