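"""Refined-set quality filters and train/validation/test manifest building.

The refined-set conditions keep complexes with X-ray resolution <= 2.5 A, a
Kd or Ki affinity with pK in [2, 12], no covalent protein-ligand bond, and a
ligand built only from the nine common heavy atoms. Manifests follow the
overlap-removal pipeline: v2016 refined minus the CASF benchmark IDs gives
the training set, v2018 refined minus (training + CASF) the validation set,
and the CSAR sets minus everything, re-filtered, the external test sets.
Overlap removal is by PDB ID.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .chem import HEAVY_ELEMENTS, normalize_element

logger = logging.getLogger(__name__)

AFFINITY_RANGE = (2.0, 12.0)
RESOLUTION_MAX = 2.5


@dataclass(frozen=True)
class ComplexRecord:
    """One indexed complex with the annotations the refined filter needs."""

    pdb_id: str
    affinity: float  # pK units (-log10 Kd or Ki, molar)
    affinity_type: str  # "Kd" | "Ki" | "IC50"
    resolution: float  # Angstrom
    covalent: bool = False
    ligand_elements: frozenset[str] = frozenset()


def refined_filter(record: ComplexRecord) -> bool:
    """True iff the record passes the four refined-set conditions."""
    for field_name in ("pdb_id", "affinity", "affinity_type", "resolution"):
        if getattr(record, field_name) in (None, ""):
            raise ValueError(f"record {record.pdb_id!r}: missing field {field_name}")
    if record.resolution > RESOLUTION_MAX:
        return False
    if record.affinity_type not in ("Kd", "Ki"):
        return False
    lo, hi = AFFINITY_RANGE
    if not (lo <= record.affinity <= hi):
        return False
    if record.covalent:
        return False
    if record.ligand_elements and not set(record.ligand_elements) <= set(HEAVY_ELEMENTS):
        return False
    return True


def remove_overlaps(
    dataset: list[ComplexRecord], exclusions: list[set[str]]
) -> list[ComplexRecord]:
    """Drop records whose PDB ID appears in any exclusion set (order kept)."""
    banned = set()
    for group in exclusions:
        banned |= {pid.lower() for pid in group}
    kept = [r for r in dataset if r.pdb_id.lower() not in banned]
    if len(kept) != len(dataset):
        logger.info("overlap removal dropped %d of %d records", len(dataset) - len(kept), len(dataset))
    return kept


_AFFINITY_RE = re.compile(r"(Kd|Ki|IC50)\s*([=<>~]+)", re.I)


def parse_index_file(path: str | Path) -> list[ComplexRecord]:
    """Parse a PDBbind-style index file.

    Expected whitespace-delimited columns: PDB code, resolution, year,
    -logKd/Ki, affinity string (e.g. ``Kd=25uM``); comment lines start
    with '#'. Records with inequality affinities keep their type but are
    marked via the parsed operator only when exact ('=' or '~').
    """
    records = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"{path}:{ln}: expected at least 5 columns")
        m = _AFFINITY_RE.search(parts[4])
        if m:
            kind = {"kd": "Kd", "ki": "Ki", "ic50": "IC50"}[m.group(1).lower()]
        else:
            kind = "IC50"
        records.append(
            ComplexRecord(
                pdb_id=parts[0],
                affinity=float(parts[3]),
                affinity_type=kind,
                resolution=float(parts[1]),
                covalent=False,
                ligand_elements=frozenset(),
            )
        )
    return records


def annotate(
    records: list[ComplexRecord],
    covalent_ids: set[str] | None = None,
    ligand_elements: dict[str, set[str]] | None = None,
) -> list[ComplexRecord]:
    """Attach covalency flags and ligand element sets from side tables."""
    covalent_ids = {i.lower() for i in (covalent_ids or set())}
    out = []
    for r in records:
        elems = ligand_elements.get(r.pdb_id) if ligand_elements else None
        out.append(
            ComplexRecord(
                r.pdb_id,
                r.affinity,
                r.affinity_type,
                r.resolution,
                covalent=r.pdb_id.lower() in covalent_ids,
                ligand_elements=frozenset(normalize_element(e) for e in elems) if elems else r.ligand_elements,
            )
        )
    return out


def _ids(records: list[ComplexRecord]) -> set[str]:
    return {r.pdb_id for r in records}


def build_manifest(
    refined_v2016: list[ComplexRecord],
    refined_v2018: list[ComplexRecord],
    casf_ids: list[set[str]],
    csar_sets: dict[str, list[ComplexRecord]] | None = None,
) -> pd.DataFrame:
    """Assemble the train/validation/test manifest.

    Training: v2016 refined minus the CASF ID lists. Validation: v2018
    refined minus (training + CASF). External tests: each CSAR set minus all
    previous splits, then passed through the refined filter.
    """
    train = remove_overlaps(refined_v2016, casf_ids)
    valid = remove_overlaps(refined_v2018, casf_ids + [_ids(train)])
    rows = [(r.pdb_id, "train", r.affinity) for r in train]
    rows += [(r.pdb_id, "valid", r.affinity) for r in valid]
    taken = [_ids(train), _ids(valid)] + casf_ids
    for name, records in (csar_sets or {}).items():
        kept = [r for r in remove_overlaps(records, taken) if refined_filter(r)]
        rows += [(r.pdb_id, name, r.affinity) for r in kept]
        taken.append(_ids(kept))
    return pd.DataFrame(rows, columns=["pdb_id", "split", "affinity"])
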