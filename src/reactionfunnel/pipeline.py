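"""End-to-end orchestration: synthesize/load data, train, enumerate, funnel.

A pipeline run is driven by a single config mapping (usually a YAML file)
and a global seed. Every stochastic component receives a named substream
derived from the global seed, so stages can be reproduced independently.
Each stage writes its artifact once into the run directory and records a
SHA-256 hash in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .chemgraph import ConditionVocabulary, encode_conditions
from .datasplit import make_split
from .enumerator import enumerate_products, write_products
from .errors import FunnelError
from .funnel import CandidateScoreCard, FunnelConfig, apply_funnel, get_scorer
from .gtnn import (
    Batch,
    DatasetEncoder,
    GTNNConfig,
    GTNNModel,
    predict_ids,
    train_fold,
)
from . import nn
from .metrics import binary_metrics, mae, pearson
from .surf import ReactionRecord, read_surf, write_surf
from .synthdata import (
    ATMOSPHERE,
    REAGENT,
    SOLVENT,
    SyntheticSpec,
    generate_dataset,
    generate_structures,
)

log = logging.getLogger("reactionfunnel")


def _seed_for(global_seed: int, stream: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    surf_path: str | None = None  # load instead of synthesizing when set
    synth: dict = dataclasses.field(default_factory=dict)
    gtnn: dict = dataclasses.field(default_factory=dict)
    split_mode: str = "0D"
    split_k: int = 4
    funnel: dict = dataclasses.field(default_factory=dict)
    n_library_scaffolds: int = 8
    n_library_acids: int = 10
    potency_scorer: str = "potency:synthetic"
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise FunnelError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def validate(self) -> None:
        if self.surf_path is not None and not Path(self.surf_path).exists():
            raise FunnelError(f"surf_path does not exist: {self.surf_path}")


def predict_pair_yield(
    model: GTNNModel,
    arene_smiles: str,
    acid_smiles: str,
    encoder: DatasetEncoder,
    conditions: list[ReactionRecord],
) -> float:
    """Best predicted yield for a coupling pair over a set of plate conditions."""
    from .chemgraph import mol_to_graph

    best = 0.0
    arene = encoder._graphs.get(arene_smiles) or mol_to_graph(arene_smiles)
    acid = encoder._graphs.get(acid_smiles) or mol_to_graph(acid_smiles)
    with nn.no_grad():
        vecs = np.stack(
            [encode_conditions(rec, model.vocab) for rec in conditions]
        )
        batch = Batch(
            Batch.assemble([arene] * len(conditions), None, model.config.mode),
            Batch.assemble([acid] * len(conditions), None, model.config.mode),
            vecs,
            len(conditions),
        )
        preds = model.forward_batch(batch).data
        best = float(preds.max())
    return best


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "artifacts": {}}

    def record_stage(name: str, t0: float, artifacts: dict) -> None:
        entry = {"stage": name, "wall_s": round(time.time() - t0, 2)}
        for label, path in artifacts.items():
            manifest["artifacts"][label] = {
                "path": str(path),
                "sha256": _sha256(Path(path)),
            }
        manifest["stages"].append(entry)
        log.info("stage %s done in %.1fs", name, entry["wall_s"])

    # -- stage 1: dataset -----------------------------------------------------
    t0 = time.time()
    if config.surf_path:
        dataset = read_surf(config.surf_path)
        spec = None
    else:
        synth_args = dict(config.synth)
        synth_args.setdefault("n_reactions", 800)
        synth_args.setdefault("n_arenes", 30)
        synth_args.setdefault("n_acids", 20)
        spec = SyntheticSpec(seed=_seed_for(config.seed, "synth"), **synth_args)
        dataset = generate_dataset(spec)
    surf_out = out / "dataset.surf"
    write_surf(dataset, surf_out)
    record_stage("dataset", t0, {"dataset": surf_out})

    # -- stage 2: split -------------------------------------------------------
    t0 = time.time()
    split = make_split(
        dataset, config.split_mode, k=config.split_k,
        seed=_seed_for(config.seed, "split"),
    )
    split_out = out / "splits.json"
    split.to_json(split_out)
    record_stage("split", t0, {"splits": split_out})

    # -- stage 3: train -------------------------------------------------------
    t0 = time.time()
    gtnn_args = dict(config.gtnn)
    gtnn_args.setdefault("seed", _seed_for(config.seed, "train"))
    gtnn_cfg = GTNNConfig.reduced(**gtnn_args)
    vocab = ConditionVocabulary(dataset.condition_vocabulary)
    encoder = DatasetEncoder(dataset, gtnn_cfg, vocab)
    result = train_fold(dataset, split.folds[0], gtnn_cfg, vocab=vocab,
                        encoder=encoder)
    model = result.best_model
    ckpt = out / "model.npz"
    model.save(ckpt)
    record_stage("train", t0, {"checkpoint": ckpt})

    # -- stage 4: evaluate ----------------------------------------------------
    t0 = time.time()
    test_ids = split.folds[0].test
    preds = predict_ids(model, encoder, test_ids)
    truth = np.array([encoder.targets[i] for i in test_ids])
    report = {
        "n_test": len(test_ids),
        "mae": mae(preds, truth),
        "pearson_r": pearson(preds, truth),
        "binary": binary_metrics(preds, truth),
        "best_epoch": result.best_epoch,
    }
    pred_out = out / "predictions.tsv"
    with open(pred_out, "w") as fh:
        fh.write("rxn_id\tpredicted_yield\tpredicted_binary\n")
        for rid, p in zip(test_ids, preds):
            fh.write(f"{rid}\t{p:.6f}\t{int(p >= 0.05)}\n")
    report_out = out / "report.json"
    report_out.write_text(json.dumps(report, indent=1))
    record_stage("evaluate", t0, {"predictions": pred_out, "report": report_out})
    manifest["evaluation"] = report

    # -- stage 5: enumerate ---------------------------------------------------
    t0 = time.time()
    lib_spec = SyntheticSpec(
        n_arenes=config.n_library_scaffolds,
        n_acids=config.n_library_acids,
        seed=_seed_for(config.seed, "library"),
    )
    scaffolds, acids = generate_structures(lib_spec)
    products = enumerate_products(scaffolds, acids)
    lib_out = out / "library.tsv"
    write_products(products, lib_out)
    record_stage("enumerate", t0, {"library": lib_out})

    # -- stage 6: score + funnel ---------------------------------------------
    t0 = time.time()
    potency = get_scorer(config.potency_scorer)
    adme = {ep: get_scorer(f"adme:toy-{n}") for ep, n in
            [("logd", "logp"), ("lysa", "lysa"), ("pgp_ratio", "pgp"),
             ("pampa", "pampa")]}
    plate = [
        ReactionRecord(
            reaction_id=f"plate{i}", arene="c1ccncc1", acid="CC(=O)O",
            catalyst=cat, additive=add, reagent=REAGENT, solvent=SOLVENT,
            atmosphere=ATMOSPHERE,
        )
        for i, (cat, add) in enumerate(
            (c, a) for c in vocab.labels["catalyst"] for a in vocab.labels["additive"]
        )
    ]
    scaffold_by_id = {s.scaffold_id: s for s in scaffolds}
    acid_by_id = {a.acid_id: a for a in acids}
    cards = []
    for p in products:
        y = predict_pair_yield(
            model, scaffold_by_id[p.scaffold_id].structure,
            acid_by_id[p.acid_id].structure, encoder, plate,
        )
        cards.append(
            CandidateScoreCard(
                scaffold_id=p.scaffold_id,
                acid_id=p.acid_id,
                pic50_pred=potency(p.product),
                yield_pred=y,
                **{ep: fn(p.product) for ep, fn in adme.items()},
            )
        )
    funnel_cfg = FunnelConfig(**config.funnel)
    funnel_result = apply_funnel(cards, funnel_cfg)
    funnel_out = out / "funnel.json"
    funnel_out.write_text(
        json.dumps(
            {
                "counts": funnel_result.counts,
                "stage3_ids": funnel_result.stage3_ids,
            },
            indent=1,
        )
    )
    ranked_out = out / "ranked.tsv"
    with open(ranked_out, "w") as fh:
        fh.write("scaffold_id\tacid_id\tpic50_pred\tyield_pred\n")
        for c in funnel_result.ranked:
            fh.write(f"{c.scaffold_id}\t{c.acid_id}\t{c.pic50_pred:.3f}\t"
                     f"{c.yield_pred:.4f}\n")
    record_stage("funnel", t0, {"funnel": funnel_out, "ranked": ranked_out})
    manifest["funnel_counts"] = funnel_result.counts

    manifest_out = out / "manifest.json"
    manifest_out.write_text(json.dumps(manifest, indent=1))
    return manifest
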