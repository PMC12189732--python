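"""Stage orchestration: featurize -> pretrain -> finetune -> evaluate -> represent.

Every stage writes into a run directory stamped with the configuration hash
and seed (``manifest.json``); re-running with identical config and seed
reproduces identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

from . import data_io, featurize, represent, train
from .config import RunConfig
from .evaluate import evaluate_split
from .model import ModelConfig, ModelState, init_model

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    pass


def _write_manifest(out: Path, config: RunConfig, stages: list[str]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps({
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
    }, indent=1))


def simulate_stage(config: RunConfig, out: Path):
    spec = data_io.SyntheticSpec(
        n_targets=config.n_targets, n_compounds=config.n_compounds,
        motif_length=config.motif_length, positive_rate=config.positive_rate,
        noise_rate=config.noise_rate, seed=config.seed,
    )
    dataset, truth = data_io.generate_synthetic_dti(spec)
    syn = out / "synthetic"
    syn.mkdir(parents=True, exist_ok=True)
    data_io.write_dti_table(dataset, syn / "pairs.tsv")
    data_io.write_fasta_targets(dataset.targets.values(), syn / "targets.fasta")
    truth.to_json(syn / "truth.json")
    return dataset, truth


def featurize_stage(config: RunConfig, dataset: data_io.DTIDataset, out: Path) -> featurize.FeatureSet:
    fc = featurize.FeaturizeConfig(
        fingerprint_radius=config.fingerprint_radius,
        fingerprint_bits=config.fingerprint_bits,
        kmer_k=config.kmer_k, kmer_dim=config.kmer_dim,
        kmer_epochs=config.kmer_epochs, seed=config.seed,
    )
    features = featurize.featurize_dataset(dataset.compounds.values(), dataset.targets.values(), fc)
    features.save(out / "features")
    return features


def _model_config(config: RunConfig, features: featurize.FeatureSet) -> ModelConfig:
    return ModelConfig(
        target_dim=features.target_dim, compound_dim=features.compound_dim,
        p=config.p, hidden=config.hidden, token_count=config.token_count,
        epsilon=config.epsilon, margin=config.margin, seed=config.seed,
    )


def pretrain_stage(config: RunConfig, dataset, features, out: Path) -> ModelState:
    tc = train.TrainConfig(
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        epochs=config.epochs, seed=config.seed,
        decoys_per_positive=config.decoys_per_positive,
        contrastive_weight=config.contrastive_weight, margin=config.margin,
    )
    state, history = train.pretrain(dataset, features, tc, model_config=_model_config(config, features))
    state.save(out / "checkpoints" / "pretrained")
    history.write_csv(out / "pretrain_history.csv")
    return state


def finetune_stage(config: RunConfig, dataset, truth, features, state: ModelState, out: Path) -> ModelState:
    tc = train.TrainConfig(
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        epochs=config.finetune_epochs, seed=config.seed,
        decoys_per_positive=config.decoys_per_positive,
        contrastive_weight=config.contrastive_weight, margin=config.margin,
    )
    decoy_sets = data_io.decoy_sets_from_truth(dataset, truth, seed=config.seed)
    triplets = train.build_triplets(decoy_sets, tc)
    state, history = train.contrastive_finetune(state, dataset, triplets, features, tc)
    state.save(out / "checkpoints" / "finetuned")
    history.write_csv(out / "finetune_history.csv")
    return state


def evaluate_stage(config: RunConfig, dataset, features, state: ModelState, out: Path):
    reports = []
    rep_dir = out / "reports"
    rep_dir.mkdir(parents=True, exist_ok=True)
    for split in ("validation", "test"):
        report = evaluate_split(state, dataset, features, split=split)
        report.to_json(rep_dir / f"eval_{split}.json")
        report.to_csv(rep_dir / f"eval_{split}.csv")
        reports.append(report)
    return reports


def represent_stage(config: RunConfig, dataset, features, state: ModelState, out: Path):
    """Per-target joint projection and distance ranking for the first target."""
    rep_dir = out / "represent"
    rep_dir.mkdir(parents=True, exist_ok=True)
    target_id = next(iter(dataset.targets))
    compound_ids = list(features.compound)
    entities = [(target_id, "target")] + [(c, "compound") for c in compound_ids]
    latents = represent.extract_latents(state, entities, features)
    projection = represent.project_2d(latents, seed=config.seed, n_neighbors=config.projection_neighbors)
    projection.to_csv(rep_dir / "projection.csv")
    labels = {c: dataset.compounds[c].class_label for c in compound_ids}
    table = represent.rank_by_distance(projection, target_id, compound_ids, class_labels=labels)
    table.to_csv(rep_dir / f"ranking_{target_id}.csv")
    return table


def run_pipeline(config: RunConfig, out: str | Path) -> dict:
    """Run all stages on synthetic data (or a provided DTI table); returns a summary."""
    out = Path(out)
    stages_done: list[str] = []
    _write_manifest(out, config, stages_done)
    try:
        if config.dti_table:
            dataset = data_io.read_dti_table(config.dti_table)
            truth = None
        else:
            dataset, truth = simulate_stage(config, out)
        stages_done.append("simulate")
        features = featurize_stage(config, dataset, out)
        stages_done.append("featurize")
        state = pretrain_stage(config, dataset, features, out)
        stages_done.append("pretrain")
        if truth is not None and config.contrastive_weight > 0:
            state = finetune_stage(config, dataset, truth, features, state, out)
            stages_done.append("finetune")
        reports = evaluate_stage(config, dataset, features, state, out)
        stages_done.append("evaluate")
        table = represent_stage(config, dataset, features, state, out)
        stages_done.append("represent")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage after {stages_done}: {exc}\n")
        _write_manifest(out, config, stages_done)
        raise StageFailure(f"pipeline failed after stages {stages_done}: {exc}") from exc
    _write_manifest(out, config, stages_done)
    return {
        "stages": stages_done,
        "reports": {r.split: asdict(r) for r in reports},
        "ranking_target": table.target_id,
        "config_hash": config.config_hash(),
    }
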