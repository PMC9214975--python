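"""File formats, configuration and the end-to-end pipeline driver.

All tabular inputs are delimited text (CSV or TSV, sniffed by delimiter);
model checkpoints and featurized graph sets are NumPy ``.npz`` archives
with a JSON sidecar/field recording the architecture, the featurizer
configuration and a content checksum. Every artifact written by
:func:`run_pipeline` embeds the seed and the configuration hash that
produced it, and stage boundaries log record counts in and out so filter
attrition is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gcn, gradcam, moieties, pkfi, synthetic
from .featurize import FeaturizerConfig, featurize_compound
from .gcn import KERNELS, ModelParams, TrainConfig
from .pkfi import KinaseFamily, RawActivityRecord

logger = logging.getLogger(__name__)

ACTIVITY_COLUMNS = ("compound_id", "smiles", "kinase_id",
                    "measure", "relation", "value")
FAMILY_COLUMNS = ("family_id", "group", "kinase_id")

VALID_MEASURES = {"IC50_nM", "pKi"}
VALID_RELATIONS = {"=", "<", ">", "~", ">>"}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _read_table(path) -> pd.DataFrame:
    # sep=None + python engine sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_activity_table(path):
    """Read raw activity records; malformed rows go to an error report.

    Returns ``(records, report)`` where ``report`` is a list of
    ``(row_number, reason)`` for rows that could not be typed. A missing
    required column raises immediately, naming the column.
    """
    df = _read_table(path)
    for col in ACTIVITY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"activity table is missing column {col!r}")
    records, report = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            value = float(row["value"])
            measure, relation = row["measure"], row["relation"]
            if measure not in VALID_MEASURES:
                raise ValueError(f"unknown measure {measure!r}")
            if relation not in VALID_RELATIONS:
                raise ValueError(f"unknown relation {relation!r}")
            records.append(RawActivityRecord(
                compound_id=row["compound_id"], smiles=row["smiles"],
                kinase_id=row["kinase_id"], measure=measure,
                relation=relation, value=value,
                source=row.get("source") or "chembl-like",
                assay_type=row.get("assay_type") or None,
                target_type=row.get("target_type") or None,
                confidence=(int(row["confidence"])
                            if row.get("confidence") else None)))
        except (ValueError, TypeError) as exc:
            report.append((i, str(exc)))
    logger.info("read_activity_table: %d records, %d malformed rows",
                len(records), len(report))
    return records, report


def write_activity_table(records, path):
    rows = [{"compound_id": r.compound_id, "smiles": r.smiles,
             "kinase_id": r.kinase_id, "measure": r.measure,
             "relation": r.relation, "value": r.value, "source": r.source}
            for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_family_table(path) -> dict:
    """Family membership table -> {family_id: KinaseFamily}."""
    df = _read_table(path)
    for col in FAMILY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"family table is missing column {col!r}")
    out = {}
    for fid, sub in df.groupby("family_id"):
        out[fid] = KinaseFamily(
            family_id=fid, group=sub["group"].iloc[0],
            member_kinase_ids=frozenset(sub["kinase_id"]))
    return out


def write_family_table(families, path):
    rows = [{"family_id": f.family_id, "group": f.group, "kinase_id": k}
            for f in families for k in sorted(f.member_kinase_ids)]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pkfi_set(pkfi_set, structures, out_dir, meta=None):
    """PKFI set as CSV (compound_id, smiles, label) + JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [{"compound_id": c, "smiles": structures.get(c, ""),
             "label": pkfi.ACTIVE} for c in sorted(pkfi_set.positives)]
    rows += [{"compound_id": c, "smiles": structures.get(c, ""),
              "label": pkfi.INACTIVE} for c in sorted(pkfi_set.negatives)]
    csv_path = out_dir / f"pkfi_{pkfi_set.family_id}.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    summary = {
        "family_id": pkfi_set.family_id,
        "n_positives": len(pkfi_set.positives),
        "n_negatives": len(pkfi_set.negatives),
        "balance": None if np.isnan(pkfi_set.balance) else pkfi_set.balance,
        "balance_flag": pkfi_set.balance_flag,
    }
    summary.update(meta or {})
    json_path = out_dir / f"pkfi_{pkfi_set.family_id}.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return csv_path, json_path


def read_pkfi_set(csv_path, family_id=None):
    """Load a PKFI set CSV back into (PKFISet, structures)."""
    df = pd.read_csv(csv_path, dtype=str)
    positives = set(df.loc[df["label"] == pkfi.ACTIVE, "compound_id"])
    negatives = set(df.loc[df["label"] == pkfi.INACTIVE, "compound_id"])
    structures = dict(zip(df["compound_id"], df["smiles"]))
    fid = family_id or Path(csv_path).stem.replace("pkfi_", "")
    return pkfi.PKFISet(family_id=fid, positives=positives,
                        negatives=negatives), structures


def _checksum(arrays: dict) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def save_model(params: ModelParams, path):
    """Checkpoint all weights + architecture JSON + content checksum."""
    params.validate()
    arrays = {f"W{l + 1}": W for l, W in enumerate(params.weights)}
    arrays["classifier_w"] = params.classifier_w
    arrays["classifier_b"] = params.classifier_b
    meta = {
        "kernels": list(params.kernels),
        "activation": params.activation,
        "n_features": params.n_features,
        "checksum": _checksum(arrays),
    }
    np.savez(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_model(path, expected_kernels=None) -> ModelParams:
    """Load a checkpoint; verifies checksum and architecture."""
    try:
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta"]))
            arrays = {k: npz[k] for k in npz.files if k != "meta"}
    except Exception as exc:
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}")
    if _checksum(arrays) != meta["checksum"]:
        raise ValueError(f"checksum mismatch in checkpoint {path}")
    kernels = tuple(meta["kernels"])
    if expected_kernels is not None and tuple(expected_kernels) != kernels:
        raise ValueError(
            f"checkpoint architecture {kernels} does not match the "
            f"configured kernels {tuple(expected_kernels)}")
    params = ModelParams(
        weights=[arrays[f"W{l + 1}"] for l in range(len(kernels))],
        classifier_w=arrays["classifier_w"],
        classifier_b=arrays["classifier_b"],
        kernels=kernels, activation=meta["activation"],
        n_features=meta["n_features"])
    params.validate()
    return params


def save_graphs(graphs: dict, path, config: FeaturizerConfig, sidecar=None):
    """Serialized graph tensors + JSON sidecar with the featurizer config."""
    path = Path(path)
    ids = sorted(graphs)
    np.savez_compressed(
        path,
        ids=np.array(ids),
        n_atoms=np.array([graphs[c].n_atoms for c in ids]),
        AF=np.stack([graphs[c].AF for c in ids]),
        L=np.stack([graphs[c].L for c in ids]))
    meta = {"featurizer": dataclasses.asdict(config),
            "n_graphs": len(ids)}
    meta.update(sidecar or {})
    side = path.with_suffix(".json")
    side.write_text(json.dumps(meta, indent=2))
    return path, side


def load_graphs(path) -> dict:
    from .featurize import CompoundGraph

    with np.load(path, allow_pickle=False) as npz:
        ids = [str(c) for c in npz["ids"]]
        return {cid: CompoundGraph(compound_id=cid,
                                   n_atoms=int(npz["n_atoms"][i]),
                                   AF=npz["AF"][i], L=npz["L"][i])
                for i, cid in enumerate(ids)}


@dataclass
class PipelineConfig:
    """One serializable configuration object for the whole pipeline."""

    adjacency_mode: str = "weighted"
    max_atoms: int = 50
    kernels: tuple = KERNELS
    activation: str = "relu"
    train: TrainConfig = field(default_factory=TrainConfig)
    gradcam_layer: int = 3
    gradcam_threshold: float = gradcam.DRAW_THRESHOLD
    split_fraction: float = 0.8
    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kernels"] = list(self.kernels)
        d["synthetic"]["motifs"] = list(self.synthetic.motifs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        train = TrainConfig(**d.pop("train", {}))
        syn = synthetic.SyntheticConfig(**{
            **d.pop("synthetic", {}),
        })
        if isinstance(syn.motifs, list):
            syn.motifs = tuple(syn.motifs)
        kernels = tuple(d.pop("kernels", KERNELS))
        return cls(train=train, synthetic=syn, kernels=kernels, **d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = PipelineConfig.from_dict(self.to_dict())
        cfg.seed = seed
        cfg.train.seed = seed
        cfg.synthetic.seed = seed
        return cfg


def featurize_set(structures: dict, config: PipelineConfig) -> dict:
    fconfig = FeaturizerConfig(adjacency_mode=config.adjacency_mode,
                               max_atoms=config.max_atoms)
    return {cid: featurize_compound(smiles, compound_id=cid, config=fconfig)
            for cid, smiles in structures.items()}


def run_pipeline(config: PipelineConfig, out_dir,
                 activities_path=None, families_path=None,
                 family_id=None, n_explain: int = 5) -> dict:
    """Run simulate/build -> featurize -> train -> evaluate -> explain ->
    moiety-stats, writing every artifact plus a JSON run manifest.

    Without ``activities_path`` the synthetic benchmark generator supplies
    the labeled set; with input tables the PKFI set is curated from them.
    Any stage failure is re-raised as :class:`PipelineStageError`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "stages": {}}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrap

    # stage 1: obtain a labeled set with structures
    if activities_path is None:
        bench = stage("build-sets")(synthetic.gen_classification_benchmark,
                                    config.synthetic)
        pkfi_set, structures = bench.pkfi_set, bench.structures
        motif_atoms = bench.motif_atoms
    else:
        if families_path is None:
            raise PipelineStageError("build-sets", "missing family table")
        records, report = stage("build-sets")(read_activity_table,
                                              activities_path)
        families = stage("build-sets")(read_family_table, families_path)
        if family_id not in families:
            raise PipelineStageError("build-sets",
                                     f"unknown family {family_id!r}")
        records = pkfi.filter_records(records)
        calls = pkfi.consensus_calls(records)
        structures = {r.compound_id: r.smiles for r in records}
        pkfi_set = stage("build-sets")(pkfi.build_pkfi_set, calls,
                                       families[family_id], structures)
        motif_atoms = {}
        manifest["stages"]["read"] = {"records": len(records),
                                      "malformed": len(report)}
    structures = {cid: structures[cid]
                  for cid in pkfi_set.positives | pkfi_set.negatives}
    write_pkfi_set(pkfi_set, structures, out_dir,
                   meta={"config_hash": config.config_hash(),
                         "seed": config.seed})
    manifest["stages"]["build-sets"] = {
        "positives": len(pkfi_set.positives),
        "negatives": len(pkfi_set.negatives),
        "balance": None if np.isnan(pkfi_set.balance) else pkfi_set.balance}

    # stage 2: featurize
    graphs = stage("featurize")(featurize_set, structures, config)
    manifest["stages"]["featurize"] = {"graphs": len(graphs)}

    # stage 3: train
    split = stage("train")(pkfi.split_set, pkfi_set,
                           config.split_fraction, config.seed)
    params = stage("train")(gcn.train, split, graphs, config.train)
    save_model(params, out_dir / "model.npz")
    manifest["stages"]["train"] = {"epochs": config.train.epochs,
                                   "final_loss": params.train_loss[-1]
                                   if params.train_loss else None}

    # stage 4: evaluate
    metrics = stage("evaluate")(gcn.evaluate, params, split.test, graphs)
    manifest["metrics"] = {
        "acc": metrics.acc, "mcc": metrics.mcc,
        "auroc": None if np.isnan(metrics.auroc) else metrics.auroc,
        "confusion": metrics.confusion.tolist(), "flag": metrics.flag}

    # stage 5: explain a few test positives
    explain_dir = out_dir / "explanations"
    explained = []
    test_pos = [cid for cid, lab in split.test if lab == pkfi.ACTIVE]
    for cid in test_pos[:n_explain]:
        maps = stage("explain")(gradcam.explain, params, graphs[cid],
                                config.gradcam_layer)
        gradcam.render(structures[cid], maps, explain_dir / cid,
                       threshold=config.gradcam_threshold)
        payload = gradcam.attention_json(structures[cid], maps)
        payload.update({"compound_id": cid,
                        "config_hash": config.config_hash(),
                        "seed": config.seed})
        (explain_dir / f"{cid}.json").write_text(json.dumps(payload, indent=2))
        explained.append(cid)
    manifest["stages"]["explain"] = {"compounds": explained}

    # stage 6: moiety enrichment
    dictionary = moieties.load_dictionary()
    rows = stage("moiety-stats")(moieties.rank_descriptors, pkfi_set,
                                 structures, dictionary)
    pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
        out_dir / "moiety_enrichment.csv", index=False)
    manifest["stages"]["moiety-stats"] = {
        "descriptors": len(rows),
        "top": {"id": rows[0].descriptor_id, "name": rows[0].name,
                "odds_ratio": rows[0].odds_ratio}}

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out_dir / "manifest.json")
    return manifest
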