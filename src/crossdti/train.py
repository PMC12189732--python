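"""Pre-training on labelled DTI pairs and contrastive fine-tuning on triplets.

Pre-training minimises the mean sigmoid-BCE over mini-batches with Adam;
the retained checkpoint is the epoch with the best validation PR AUC.
Fine-tuning alternates BCE mini-batches with triplet-hinge mini-batches built
from per-target decoy pools (default 50 randomly sampled decoys per active,
drawn without replacement).  All shuffling and sampling is driven by per-epoch
seeded streams so that runs are bit-reproducible and a contrastive weight of
zero consumes exactly the same random stream as continued pre-training.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import DecoySet, DTIDataset
from .featurize import FeatureSet
from .model import ModelState, bce_backward, triplet_backward, forward, sigmoid
from .evaluate import pr_auc

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    decoys_per_positive: int = 50
    contrastive_weight: float = 1.0
    margin: float = 1.0
    triplet_batch_size: int = 4  # triplet sets per contrastive step

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.decoys_per_positive < 1:
            raise ValueError("decoys_per_positive must be >= 1")
        if self.contrastive_weight < 0:
            raise ValueError("contrastive_weight must be non-negative")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class TripletSet:
    anchor: str  # target id
    positive: str  # active compound id
    negatives: list[str]


@dataclass
class EpochRecord:
    epoch: int
    bce: float
    triplet: float
    val_pr_auc: float


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)
    best_epoch: int = -1

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "bce", "triplet", "val_pr_auc"])
            for r in self.records:
                writer.writerow([r.epoch, r.bce, r.triplet, r.val_pr_auc])


class Adam:
    """Standard Adam with bias correction; state keyed like the parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _pair_matrices(pairs, features: FeatureSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    usable = [p for p in pairs if p.compound_id in features.compound and p.target_id in features.target]
    E1 = np.stack([features.target[p.target_id].vector for p in usable])
    E2 = np.stack([features.compound[p.compound_id].vector for p in usable])
    y = np.array([p.label for p in usable], dtype=np.float64)
    return E1, E2, y


def _validation_pr_auc(state: ModelState, E1v, E2v, yv) -> float:
    scores = sigmoid(forward(E1v, E2v, state))
    return pr_auc(scores, yv)


def _bce_epoch(state, opt, E1, E2, y, batch_size, rng) -> float:
    order = rng.permutation(len(y))
    total, n_batches = 0.0, 0
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        loss, grads = bce_backward(E1[idx], E2[idx], y[idx], state)
        opt.step(state.params, grads)
        total += loss
        n_batches += 1
    return total / max(n_batches, 1)


def pretrain(
    dataset: DTIDataset,
    features: FeatureSet,
    config: TrainConfig,
    init_state: ModelState | None = None,
    model_config=None,
) -> tuple[ModelState, TrainingHistory]:
    """Mini-batch Adam on sigmoid-BCE; retains the best-validation-PR-AUC epoch.

    ``init_state`` continues training from an existing state (used by the
    degenerate contrastive_weight=0 fine-tuning path); otherwise a fresh
    model is initialised from ``model_config``.
    """
    from .model import ModelConfig, init_model

    train_pairs = dataset.split("train")
    val_pairs = dataset.split("validation")
    labels = {p.label for p in train_pairs}
    if not train_pairs or labels != {0, 1}:
        raise ValueError("training split must be non-empty and contain both labels")
    if not val_pairs or {p.label for p in val_pairs} != {0, 1}:
        raise ValueError("validation split must contain both labels (PR AUC undefined otherwise)")

    if init_state is None:
        if model_config is None:
            model_config = ModelConfig(
                target_dim=features.target_dim, compound_dim=features.compound_dim, seed=config.seed
            )
        state = init_model(model_config)
    else:
        state = init_state.copy()

    E1, E2, y = _pair_matrices(train_pairs, features)
    E1v, E2v, yv = _pair_matrices(val_pairs, features)

    opt = Adam(state.params, lr=config.learning_rate)
    history = TrainingHistory(seed=config.seed, config=asdict(config))
    best_state, best_auc = state.copy(), -np.inf
    for epoch in range(config.epochs):
        rng = np.random.default_rng((config.seed, epoch))
        mean_bce = _bce_epoch(state, opt, E1, E2, y, config.batch_size, rng)
        val_auc = _validation_pr_auc(state, E1v, E2v, yv)
        history.records.append(EpochRecord(epoch, mean_bce, 0.0, val_auc))
        if val_auc > best_auc:
            best_auc, best_state, history.best_epoch = val_auc, state.copy(), epoch
        logger.info("pretrain epoch %d: bce=%.4f val_pr_auc=%.4f", epoch, mean_bce, val_auc)
    return best_state, history


def build_triplets(decoy_sets: list[DecoySet], config: TrainConfig) -> list[TripletSet]:
    """One TripletSet per (target, active): the anchor, the active as positive
    and ``decoys_per_positive`` decoys sampled randomly without replacement.

    Pools smaller than the requested count contribute the whole pool, with a
    logged shortfall; targets with an empty pool are skipped with a warning.
    """
    rng = np.random.default_rng(config.seed)
    triplets: list[TripletSet] = []
    for ds in decoy_sets:
        if not ds.decoys:
            logger.warning("target %s: empty decoy pool, skipped", ds.target_id)
            continue
        decoy_ids = [d.compound_id for d in ds.decoys]
        for active in ds.actives:
            pool = [d for d in decoy_ids if d != active.compound_id]
            k = min(config.decoys_per_positive, len(pool))
            if k < config.decoys_per_positive:
                logger.info("target %s active %s: decoy shortfall (%d < %d)",
                            ds.target_id, active.compound_id, k, config.decoys_per_positive)
            chosen = list(rng.choice(len(pool), size=k, replace=False))
            triplets.append(TripletSet(
                anchor=ds.target_id,
                positive=active.compound_id,
                negatives=[pool[i] for i in chosen],
            ))
    return triplets


def margin_violation_rate(state: ModelState, triplets: list[TripletSet],
                          features: FeatureSet, margin: float) -> float:
    """Fraction of (anchor, positive, negative) probes violating the margin."""
    from .model import project

    violations, total = 0, 0
    for ts in triplets:
        a = project(features.target[ts.anchor].vector[None, :], state, "target")[0]
        p = project(features.compound[ts.positive].vector[None, :], state, "compound")[0]
        negs = np.stack([features.compound[n].vector for n in ts.negatives])
        n_lat = project(negs, state, "compound")
        d_ap = np.linalg.norm(a - p)
        d_an = np.linalg.norm(a - n_lat, axis=1)
        violations += int((d_ap - d_an + margin > 0).sum())
        total += len(ts.negatives)
    return violations / total


def contrastive_finetune(
    state: ModelState,
    dataset: DTIDataset,
    triplets: list[TripletSet],
    features: FeatureSet,
    config: TrainConfig,
) -> tuple[ModelState, TrainingHistory]:
    """Alternate BCE mini-batches on labelled pairs with triplet-hinge steps.

    The combined objective is bce + contrastive_weight * triplet.  When the
    contrastive weight is zero the triplet steps are skipped entirely, which
    makes the run identical to continued pre-training under the same seed.
    """
    if config.contrastive_weight == 0.0:
        return pretrain(dataset, features, config, init_state=state)
    if not triplets:
        raise ValueError("triplets must be non-empty for contrastive fine-tuning")

    train_pairs = dataset.split("train")
    val_pairs = dataset.split("validation")
    E1, E2, y = _pair_matrices(train_pairs, features)
    E1v, E2v, yv = _pair_matrices(val_pairs, features)

    state = state.copy()
    opt = Adam(state.params, lr=config.learning_rate)
    history = TrainingHistory(seed=config.seed, config=asdict(config))
    best_state, best_auc = state.copy(), -np.inf
    for epoch in range(config.epochs):
        rng = np.random.default_rng((config.seed, epoch))
        rng_tri = np.random.default_rng((config.seed, 100_000 + epoch))
        order = rng.permutation(len(y))
        tri_order = rng_tri.permutation(len(triplets))
        tri_pos = 0
        total_bce, total_tri, n_bce, n_tri = 0.0, 0.0, 0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = bce_backward(E1[idx], E2[idx], y[idx], state)
            opt.step(state.params, grads)
            total_bce += loss
            n_bce += 1
            # one contrastive step per BCE step, cycling through the triplets
            batch_grads = None
            batch_loss = 0.0
            for _ in range(config.triplet_batch_size):
                ts = triplets[tri_order[tri_pos % len(tri_order)]]
                tri_pos += 1
                a = features.target[ts.anchor].vector
                p = features.compound[ts.positive].vector
                negs = np.stack([features.compound[n].vector for n in ts.negatives])
                loss_t, grads_t = triplet_backward(a[None, :], p[None, :], negs, state, config.margin)
                batch_loss += loss_t
                if batch_grads is None:
                    batch_grads = grads_t
                else:
                    for k in batch_grads:
                        batch_grads[k] += grads_t[k]
            scale = config.contrastive_weight / config.triplet_batch_size
            for k in batch_grads:
                batch_grads[k] *= scale
            opt.step(state.params, batch_grads)
            total_tri += batch_loss / config.triplet_batch_size
            n_tri += 1
        val_auc = _validation_pr_auc(state, E1v, E2v, yv)
        history.records.append(EpochRecord(epoch, total_bce / max(n_bce, 1),
                                           total_tri / max(n_tri, 1), val_auc))
        if val_auc > best_auc:
            best_auc, best_state, history.best_epoch = val_auc, state.copy(), epoch
        logger.info("finetune epoch %d: bce=%.4f triplet=%.4f val_pr_auc=%.4f",
                    epoch, total_bce / max(n_bce, 1), total_tri / max(n_tri, 1), val_auc)
    return best_state, history
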