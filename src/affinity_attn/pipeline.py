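"""Featurize -> select -> train -> predict -> evaluate orchestration.

A run is described by a YAML config (see :class:`RunConfig`) and a manifest
CSV listing complexes with columns ``id``, ``affinity``, ``split`` (train /
valid / test) and either ``structure_path`` (internal JSON) or
``protein_path`` + ``ligand_path`` (PDB + MOL2/SDF). Each stage writes its
artifact into the work directory together with a content-hash stamp, so
rerunning a completed stage with unchanged inputs is a no-op and downstream
stages are resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import DESCRIPTOR_CUTOFF, VINA_CUTOFF
from .complex_io import ComplexStructure, load_complex, read_json
from .descriptors import (
    DescriptorVocabulary,
    extract_descriptor_counts,
    select_top_descriptors,
)
from .evaluation import regression_metrics
from .model import Model, ModelConfig, predict_batch, train_model
from .vina_terms import compute_vina_features

logger = logging.getLogger(__name__)

STAGES = ("featurize", "select", "train", "predict", "evaluate")


class MissingArtifactError(FileNotFoundError):
    """An upstream stage has not produced its artifact yet."""


@dataclass
class RunConfig:
    """Paths, cutoffs, seeds and model settings for one pipeline run."""

    manifest: str
    workdir: str
    seed: int = 0
    cutoff: float = DESCRIPTOR_CUTOFF
    vina_cutoff: float = VINA_CUTOFF
    select_u: int | None = None  # None keeps the full vocabulary
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    use_vina: bool = True
    use_attention: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "workdir": self.workdir,
            "seed": self.seed,
            "cutoff": self.cutoff,
            "vina_cutoff": self.vina_cutoff,
            "select_u": self.select_u,
            "model": self.model,
            "use_vina": self.use_vina,
            "use_attention": self.use_attention,
        }


def _hash_inputs(*parts: str) -> str:
    digest = hashlib.sha256()
    for part in parts:
        digest.update(part.encode())
        digest.update(b"\0")
    return digest.hexdigest()


def _stamp_path(workdir: Path, stage: str) -> Path:
    return workdir / f".{stage}.stamp"


def _is_current(workdir: Path, stage: str, content_hash: str, outputs: list[Path]) -> bool:
    stamp = _stamp_path(workdir, stage)
    return (
        stamp.exists()
        and stamp.read_text().strip() == content_hash
        and all(p.exists() for p in outputs)
    )


def _load_structure(row: pd.Series, base: Path) -> ComplexStructure:
    if isinstance(row.get("structure_path"), str) and row["structure_path"]:
        return read_json(base / row["structure_path"])
    return load_complex(base / row["protein_path"], base / row["ligand_path"], row["id"])


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"{path} is missing; run the '{producer}' stage first"
        )
    return path


def run_pipeline(config: RunConfig, stage: str = "all") -> dict[str, Path]:
    """Execute one stage (or all stages in order); returns artifact paths."""
    if stage != "all" and stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(workdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        stages = STAGES if stage == "all" else (stage,)
        artifacts: dict[str, Path] = {}
        for s in stages:
            artifacts.update(_STAGE_FUNCS[s](config, workdir))
        return artifacts
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage_featurize(config: RunConfig, workdir: Path) -> dict[str, Path]:
    manifest_path = Path(config.manifest)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    out_desc = workdir / "descriptors.csv"
    out_vina = workdir / "vina.csv"
    chash = _hash_inputs("featurize", manifest_path.read_text(), str(config.cutoff), str(config.vina_cutoff))
    if _is_current(workdir, "featurize", chash, [out_desc, out_vina]):
        logger.info("featurize: up to date, skipping")
        return {"descriptors": out_desc, "vina": out_vina}
    desc_rows, vina_rows = [], []
    for _, row in manifest.iterrows():
        structure = _load_structure(row, base)
        counts = extract_descriptor_counts(structure, config.cutoff)
        desc_rows += [(row["id"], key, n) for key, n in sorted(counts.items())]
        terms = compute_vina_features(structure, config.vina_cutoff)
        vina_rows.append((row["id"], *terms.as_tuple()))
    pd.DataFrame(desc_rows, columns=["id", "descriptor", "count"]).to_csv(out_desc, index=False)
    pd.DataFrame(
        vina_rows,
        columns=["id", "gauss1", "gauss2", "repulsion", "hydrophobic", "hbond", "n_rot"],
    ).to_csv(out_vina, index=False)
    _stamp_path(workdir, "featurize").write_text(chash)
    logger.info("featurize: %d complexes, %d descriptor rows", len(manifest), len(desc_rows))
    return {"descriptors": out_desc, "vina": out_vina}


def _stage_select(config: RunConfig, workdir: Path) -> dict[str, Path]:
    manifest = pd.read_csv(config.manifest)
    desc_path = _require(workdir / "descriptors.csv", "featurize")
    out_vocab = workdir / "vocab.json"
    chash = _hash_inputs("select", desc_path.read_text(), str(config.select_u), str(config.seed))
    if _is_current(workdir, "select", chash, [out_vocab]):
        logger.info("select: up to date, skipping")
        return {"vocab": out_vocab}
    counts = pd.read_csv(desc_path)
    train_ids = set(manifest.loc[manifest["split"] == "train", "id"])
    train_counts = counts[counts["id"].isin(train_ids)]
    vocab = DescriptorVocabulary(sorted(train_counts["descriptor"].unique()))
    if config.select_u is not None and config.select_u < len(vocab):
        X = _count_matrix(train_counts, vocab, sorted(train_ids))
        y = (
            manifest.set_index("id")
            .loc[sorted(train_ids), "affinity"]
            .to_numpy(dtype=float)
        )
        vocab = select_top_descriptors(X, y, config.select_u, config.seed, vocab)
    out_vocab.write_text(
        json.dumps(
            {
                "entries": vocab.entries,
                "metadata": {"cutoff": config.cutoff, "u": len(vocab), "seed": config.seed},
            },
            indent=1,
        )
    )
    _stamp_path(workdir, "select").write_text(chash)
    logger.info("select: vocabulary of %d descriptors", len(vocab))
    return {"vocab": out_vocab}


def _count_matrix(counts: pd.DataFrame, vocab: DescriptorVocabulary, ids: list) -> np.ndarray:
    X = np.zeros((len(ids), len(vocab)), dtype=float)
    id_pos = {cid: i for i, cid in enumerate(ids)}
    for cid, key, n in counts.itertuples(index=False):
        row = id_pos.get(cid)
        col = vocab.index.get(key)
        if row is not None and col is not None:
            X[row, col] = n
    return X


def load_vocabulary(path: str | Path) -> DescriptorVocabulary:
    data = json.loads(Path(path).read_text())
    return DescriptorVocabulary(data["entries"])


def _split_features(config: RunConfig, workdir: Path, vocab: DescriptorVocabulary):
    manifest = pd.read_csv(config.manifest)
    counts = pd.read_csv(_require(workdir / "descriptors.csv", "featurize"))
    vina = pd.read_csv(_require(workdir / "vina.csv", "featurize")).set_index("id")
    out = {}
    for split in ("train", "valid", "test"):
        ids = list(manifest.loc[manifest["split"] == split, "id"])
        if not ids:
            out[split] = ([], [], [])
            continue
        X = _count_matrix(counts, vocab, ids)
        V = vina.loc[ids].to_numpy(dtype=float)
        y = manifest.set_index("id").loc[ids, "affinity"].to_numpy(dtype=float)
        out[split] = (X, V, y)
    return out


def _stage_train(config: RunConfig, workdir: Path) -> dict[str, Path]:
    vocab = load_vocabulary(_require(workdir / "vocab.json", "select"))
    out_model = workdir / "model.ckpt"
    out_history = workdir / "history.json"
    chash = _hash_inputs(
        "train",
        (workdir / "vocab.json").read_text(),
        (workdir / "descriptors.csv").read_text(),
        json.dumps(config.model, sort_keys=True),
        str((config.seed, config.use_vina, config.use_attention)),
    )
    if _is_current(workdir, "train", chash, [out_model]):
        logger.info("train: up to date, skipping")
        return {"model": out_model, "history": out_history}
    splits = _split_features(config, workdir, vocab)
    Xtr, Vtr, ytr = splits["train"]
    Xva, Vva, yva = splits["valid"]
    overrides = dict(config.model)
    overrides.update(
        u=len(vocab), seed=config.seed, use_vina=config.use_vina, use_attention=config.use_attention
    )
    model_config = ModelConfig(**overrides)
    train_set = list(zip(Xtr, Vtr, ytr))
    valid_set = list(zip(Xva, Vva, yva))
    model, history = train_model(train_set, valid_set, model_config)
    model.save(out_model)
    out_history.write_text(json.dumps(history, indent=1))
    _stamp_path(workdir, "train").write_text(chash)
    logger.info("train: %d epochs run, final train loss %.4f", len(history["train_loss"]), history["train_loss"][-1])
    return {"model": out_model, "history": out_history}


def _stage_predict(config: RunConfig, workdir: Path) -> dict[str, Path]:
    model_path = _require(workdir / "model.ckpt", "train")
    out_pred = workdir / "predictions.csv"
    chash = _hash_inputs("predict", str(model_path.stat().st_mtime_ns), (workdir / "vocab.json").read_text())
    if _is_current(workdir, "predict", chash, [out_pred]):
        logger.info("predict: up to date, skipping")
        return {"predictions": out_pred}
    vocab = load_vocabulary(workdir / "vocab.json")
    model = Model.load(model_path)
    manifest = pd.read_csv(config.manifest)
    splits = _split_features(config, workdir, vocab)
    X, V, y = splits["test"]
    ids = list(manifest.loc[manifest["split"] == "test", "id"])
    if len(ids) == 0:
        raise ValueError("manifest has no test split to predict on")
    pred, _ = predict_batch(model, np.asarray(X), np.asarray(V))
    pd.DataFrame({"id": ids, "y_true": y, "y_pred": pred}).to_csv(out_pred, index=False)
    _stamp_path(workdir, "predict").write_text(chash)
    logger.info("predict: %d test complexes", len(ids))
    return {"predictions": out_pred}


def _stage_evaluate(config: RunConfig, workdir: Path) -> dict[str, Path]:
    pred_path = _require(workdir / "predictions.csv", "predict")
    out_metrics = workdir / "metrics.csv"
    chash = _hash_inputs("evaluate", pred_path.read_text())
    if _is_current(workdir, "evaluate", chash, [out_metrics]):
        logger.info("evaluate: up to date, skipping")
        return {"metrics": out_metrics}
    table = pd.read_csv(pred_path)
    metrics = regression_metrics(table["y_true"], table["y_pred"])
    pd.DataFrame([metrics.as_dict()]).to_csv(out_metrics, index=False)
    _stamp_path(workdir, "evaluate").write_text(chash)
    logger.info("evaluate: %s", metrics)
    return {"metrics": out_metrics}


_STAGE_FUNCS = {
    "featurize": _stage_featurize,
    "select": _stage_select,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
}
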