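"""Featurization: Morgan fingerprints for compounds, k-mer skip-gram
embeddings for protein targets.

Compounds become fixed-length circular-substructure bit vectors (ECFP-style
Morgan hashing after SMILES canonicalization).  Proteins are decomposed into
overlapping k-mers over the three reading frames (offsets 0, 1, 2), a
skip-gram embedding table is trained on that k-mer corpus, and a protein's
vector is the mean (or sum) of its k-mer vectors — the ProtVec recipe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .data_io import CompoundRecord, TargetRecord
from .skipgram import train_sgns

logger = logging.getLogger(__name__)


class FeaturizationError(ValueError):
    """Raised when an entity cannot be featurized (e.g. unparsable SMILES)."""


@dataclass
class FingerprintVector:
    bits: np.ndarray
    n_bits: int
    radius: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.float64)
        if self.bits.shape != (self.n_bits,):
            raise ValueError("bit vector length must equal n_bits")
        if not np.isin(self.bits, (0.0, 1.0)).all():
            raise ValueError("fingerprint entries must be 0/1")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass
class KmerEmbeddingTable:
    k: int
    dim: int
    vectors: dict[str, np.ndarray]
    training_seed: int = 0

    def __post_init__(self) -> None:
        for kmer, vec in self.vectors.items():
            if len(kmer) != self.k or kmer != kmer.upper():
                raise ValueError(f"key {kmer!r} is not an uppercase {self.k}-mer")
            if np.asarray(vec).shape != (self.dim,):
                raise ValueError(f"vector for {kmer!r} has wrong length")

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.vec`` (token + floats per line) and a JSON sidecar."""
        prefix = Path(prefix)
        with open(f"{prefix}.vec", "w") as fh:
            for kmer in sorted(self.vectors):
                vals = " ".join(repr(float(x)) for x in self.vectors[kmer])
                fh.write(f"{kmer} {vals}\n")
        Path(f"{prefix}.json").write_text(
            json.dumps({"k": self.k, "dim": self.dim, "training_seed": self.training_seed})
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "KmerEmbeddingTable":
        prefix = Path(prefix)
        meta = json.loads(Path(f"{prefix}.json").read_text())
        vectors: dict[str, np.ndarray] = {}
        with open(f"{prefix}.vec") as fh:
            for line in fh:
                parts = line.split()
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        return cls(k=meta["k"], dim=meta["dim"], vectors=vectors, training_seed=meta["training_seed"])


@dataclass
class EntityEmbedding:
    entity_id: str
    modality: Literal["target", "compound"]
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.isfinite(self.vector).all():
            raise ValueError(f"non-finite embedding for {self.entity_id}")


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> FingerprintVector:
    """Hash a molecule's circular substructures into an ``n_bits`` bit vector.

    The SMILES is parsed and canonicalized by RDKit first, so any equivalent
    atom ordering of the same molecule yields identical bits.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits)
    bits[list(fp.GetOnBits())] = 1.0
    return FingerprintVector(bits=bits, n_bits=n_bits, radius=radius)


def kmer_frames(sequence: str, k: int) -> list[list[str]]:
    """Non-overlapping k-mer sentences for the three reading frames.

    Frame f takes k-mers starting at f, f+k, f+2k, ... — three shifted
    tokenisations whose union covers every position of the sequence.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    sequence = sequence.upper()
    frames = []
    for offset in range(3):
        frame = [sequence[i : i + k] for i in range(offset, len(sequence) - k + 1, k)]
        frames.append([m for m in frame if len(m) == k])
    return frames


def train_kmer_embeddings(
    sequences: Iterable[str],
    k: int = 3,
    dim: int = 100,
    seed: int = 0,
    epochs: int = 5,
    window: int = 5,
) -> KmerEmbeddingTable:
    """Train skip-gram k-mer vectors on a protein corpus (all three frames)."""
    sentences: list[list[str]] = []
    for seq in sequences:
        if len(seq) >= k:
            sentences.extend(kmer_frames(seq, k))
    if not sentences:
        raise ValueError(f"no sequence of length >= k={k} in corpus")
    vectors = train_sgns(sentences, dim=dim, window=window, epochs=epochs, seed=seed)
    return KmerEmbeddingTable(k=k, dim=dim, vectors=vectors, training_seed=seed)


def embed_protein(
    sequence: str,
    table: KmerEmbeddingTable,
    pooling: Literal["sum", "mean"] = "mean",
) -> EntityEmbedding:
    """Pool a protein's k-mer vectors over the three reading frames.

    K-mers absent from the table contribute a zero vector; the number of
    misses is logged.  ``mean`` divides by the total k-mer count (including
    misses), so the norm is bounded by the largest k-mer vector norm.
    """
    frames = kmer_frames(sequence, table.k)
    total = np.zeros(table.dim)
    n_tokens = 0
    n_miss = 0
    for frame in frames:
        for kmer in frame:
            n_tokens += 1
            vec = table.vectors.get(kmer)
            if vec is None:
                n_miss += 1
            else:
                total += vec
    if n_miss:
        logger.info("embed_protein: %d/%d k-mers missing from table", n_miss, n_tokens)
    if pooling == "mean":
        total = total / n_tokens
    elif pooling != "sum":
        raise ValueError(f"unknown pooling {pooling!r}")
    return EntityEmbedding(entity_id="", modality="target", vector=total)


@dataclass
class FeaturizeConfig:
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    kmer_k: int = 3
    kmer_dim: int = 100
    kmer_epochs: int = 5
    kmer_window: int = 5
    pooling: Literal["sum", "mean"] = "mean"
    standardize_targets: bool = True  # z-score target embeddings across the dataset
    seed: int = 0


@dataclass
class FeatureSet:
    """Embeddings for all valid entities of a dataset, keyed by entity id."""

    compound: dict[str, EntityEmbedding] = field(default_factory=dict)
    target: dict[str, EntityEmbedding] = field(default_factory=dict)
    table: KmerEmbeddingTable | None = None
    skipped_compounds: list[str] = field(default_factory=list)

    @property
    def compound_dim(self) -> int:
        return next(iter(self.compound.values())).vector.shape[0]

    @property
    def target_dim(self) -> int:
        return next(iter(self.target.values())).vector.shape[0]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "embeddings.npz",
            **{f"compound/{k}": v.vector for k, v in self.compound.items()},
            **{f"target/{k}": v.vector for k, v in self.target.items()},
        )
        if self.table is not None:
            self.table.save(directory / "kmer_table")

    @classmethod
    def load(cls, directory: str | Path) -> "FeatureSet":
        directory = Path(directory)
        data = np.load(directory / "embeddings.npz")
        fs = cls()
        for key in data.files:
            modality, eid = key.split("/", 1)
            emb = EntityEmbedding(entity_id=eid, modality=modality, vector=data[key])
            getattr(fs, modality)[eid] = emb
        if (directory / "kmer_table.vec").exists():
            fs.table = KmerEmbeddingTable.load(directory / "kmer_table")
        return fs


def featurize_dataset(
    compounds: Iterable[CompoundRecord],
    targets: Iterable[TargetRecord],
    config: FeaturizeConfig | None = None,
    table: KmerEmbeddingTable | None = None,
) -> FeatureSet:
    """Featurize every valid entity; invalid compounds are skipped and logged.

    The k-mer table is trained on the given targets' sequences unless a
    pre-trained ``table`` is supplied.
    """
    config = config or FeaturizeConfig()
    targets = list(targets)
    if table is None:
        table = train_kmer_embeddings(
            (t.sequence for t in targets),
            k=config.kmer_k,
            dim=config.kmer_dim,
            seed=config.seed,
            epochs=config.kmer_epochs,
            window=config.kmer_window,
        )
    fs = FeatureSet(table=table)
    for c in compounds:
        if not c.valid or c.smiles is None:
            fs.skipped_compounds.append(c.compound_id)
            continue
        fp = morgan_fingerprint(c.smiles, radius=config.fingerprint_radius, n_bits=config.fingerprint_bits)
        fs.compound[c.compound_id] = EntityEmbedding(
            entity_id=c.compound_id, modality="compound", vector=fp.bits
        )
    if fs.skipped_compounds:
        logger.warning("skipped %d compound(s) without valid SMILES: %s",
                       len(fs.skipped_compounds), fs.skipped_compounds[:10])
    for t in targets:
        emb = embed_protein(t.sequence, table, pooling=config.pooling)
        emb.entity_id = t.target_id
        fs.target[t.target_id] = emb
    if config.standardize_targets and len(fs.target) > 1:
        # pooled k-mer vectors have tiny, collinear scales; per-dimension
        # z-scoring across the target collection conditions the projection input
        mat = np.stack([e.vector for e in fs.target.values()])
        mu, sd = mat.mean(axis=0), mat.std(axis=0)
        sd[sd == 0] = 1.0
        for e in fs.target.values():
            e.vector = (e.vector - mu) / sd
    return fs
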