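"""Run configuration: strict schema, JSON/YAML loading, stable hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    """All knobs of the pipeline; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # data / synthetic generator
    n_targets: int = Field(40, gt=0)
    n_compounds: int = Field(200, gt=0)
    motif_length: int = Field(5, gt=0)
    positive_rate: float = Field(0.25, gt=0.0, lt=1.0)
    noise_rate: float = Field(0.0, ge=0.0, lt=0.5)
    dti_table: str | None = None
    decoy_dir: str | None = None

    # featurization
    fingerprint_radius: int = Field(2, gt=0)
    fingerprint_bits: int = Field(512, gt=0)
    kmer_k: int = Field(3, gt=0)
    kmer_dim: int = Field(32, gt=0)
    kmer_epochs: int = Field(3, gt=0)

    # model
    p: int = Field(64, gt=0)
    hidden: int | None = Field(None)
    token_count: int = Field(2, gt=0)
    epsilon: float = Field(1e-5, gt=0)
    margin: float = Field(1.0, gt=0)

    # training
    learning_rate: float = Field(1e-3, gt=0)
    batch_size: int = Field(64, gt=0)
    epochs: int = Field(60, gt=0)
    finetune_epochs: int = Field(10, gt=0)
    decoys_per_positive: int = Field(50, ge=1)
    contrastive_weight: float = Field(1.0, ge=0.0)

    # projection / misc
    projection_neighbors: int = Field(10, gt=1)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from a JSON or YAML file, filling defaults.

    Unknown keys raise :class:`ConfigError` naming the key; out-of-range
    values raise with the violated constraint.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text) or {}
        else:
            try:
                data = json.loads(text) if text.strip() else {}
            except json.JSONDecodeError:
                data = yaml.safe_load(text) or {}
    data.update(overrides)
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(str(exc)) from exc
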