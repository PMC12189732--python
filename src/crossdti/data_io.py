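"""Readers, writers and synthetic fixtures for drug-target interaction data.

Handles labelled DTI pair tables (compound SMILES, protein sequence, binary
label, split), DUD-E-style per-target directories of active/decoy SMILES,
natural-compound tables, curated clinical compound lists and FASTA target
sequences.  A seeded synthetic generator plants joint chemical/sequence motif
structure so that every downstream stage (featurization, training, ranking)
is testable without any external download.
"""

from __future__ import annotations

import csv
import json
import logging
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

CLASS_LABELS = frozenset(
    {
        "antiarrhythmic_class_1",
        "antiarrhythmic_class_2",
        "antiarrhythmic_class_3",
        "antiarrhythmic_class_4",
        "antiarrhythmic_other",
        "anticoagulant",
        "natural",
        "active",
        "decoy",
        "unknown",
    }
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class DataFormatError(ValueError):
    """A file does not conform to the expected on-disk schema."""


@dataclass
class CompoundRecord:
    """A drug or natural compound; ``valid`` is False when the SMILES does not parse."""

    compound_id: str
    name: str = ""
    smiles: str | None = None
    class_label: str = "unknown"
    valid: bool = True

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.smiles is not None and self.smiles != "":
            self.valid = Chem.MolFromSmiles(self.smiles) is not None
        else:
            self.smiles = None
            self.valid = False


@dataclass
class TargetRecord:
    """A protein target identified by id/gene symbol with an amino-acid sequence."""

    target_id: str
    sequence: str
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValueError("target_id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(
                f"target {self.target_id}: non-standard residues {sorted(bad)}"
            )


@dataclass
class InteractionPair:
    compound_id: str
    target_id: str
    label: int
    split: str = "train"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.split not in ("train", "validation", "test"):
            raise ValueError(f"unknown split {self.split!r}")


@dataclass
class DecoySet:
    """Actives and decoys for one target, used to build contrastive triplets."""

    target_id: str
    actives: list[CompoundRecord]
    decoys: list[CompoundRecord]

    def __post_init__(self) -> None:
        active_ids = {c.compound_id for c in self.actives}
        decoy_ids = {c.compound_id for c in self.decoys}
        if active_ids & decoy_ids:
            raise ValueError(
                f"target {self.target_id}: actives and decoys overlap: "
                f"{sorted(active_ids & decoy_ids)}"
            )


@dataclass
class DTIDataset:
    """A pair collection with its referenced compound and target records."""

    compounds: dict[str, CompoundRecord]
    targets: dict[str, TargetRecord]
    pairs: list[InteractionPair]

    def split(self, name: str) -> list[InteractionPair]:
        return [p for p in self.pairs if p.split == name]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-structure synthetic DTI generator."""

    n_targets: int = 40
    n_compounds: int = 200
    motif_length: int = 7
    positive_rate: float = 0.25
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets <= 0 or self.n_compounds <= 0 or self.motif_length <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive_rate must lie in (0, 1)")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# Delimited DTI tables
# ---------------------------------------------------------------------------

REQUIRED_DTI_COLUMNS = ("compound_id", "smiles", "target_id", "sequence", "label")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_dti_table(
    path: str | Path, split_map: Mapping[str, str] | None = None, default_split: str = "train"
) -> DTIDataset:
    """Read a TSV/CSV table of labelled compound-target pairs.

    Canonical columns: compound_id, smiles, target_id, sequence, label and an
    optional split column.  ``split_map`` overrides the split per compound-target
    key ``"<compound_id>|<target_id>"``; otherwise the file's split column or
    ``default_split`` is used.  Compounds and targets are deduplicated by id.
    Malformed rows raise :class:`DataFormatError` carrying 1-based line numbers.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise DataFormatError(f"{path}: empty file, no header")
        delim = _sniff_delimiter(header_line)
        columns = [c.strip() for c in header_line.rstrip("\n").split(delim)]
        missing = [c for c in REQUIRED_DTI_COLUMNS if c not in columns]
        if missing:
            raise DataFormatError(f"{path}: missing required column(s) {missing}")
        reader = csv.DictReader(fh, fieldnames=columns, delimiter=delim)

        compounds: dict[str, CompoundRecord] = {}
        targets: dict[str, TargetRecord] = {}
        pairs: list[InteractionPair] = []
        row_errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                label = int(str(row["label"]).strip())
                if label not in (0, 1):
                    raise ValueError
            except (ValueError, TypeError):
                row_errors.append(f"line {lineno}: unparsable label {row.get('label')!r}")
                continue
            cid = row["compound_id"].strip()
            tid = row["target_id"].strip()
            if not cid or not tid:
                row_errors.append(f"line {lineno}: empty compound or target id")
                continue
            if cid not in compounds:
                compounds[cid] = CompoundRecord(compound_id=cid, smiles=row["smiles"].strip())
            if tid not in targets:
                targets[tid] = TargetRecord(target_id=tid, sequence=row["sequence"].strip())
            split = (row.get("split") or default_split).strip()
            if split_map is not None:
                split = split_map.get(f"{cid}|{tid}", split)
            pairs.append(InteractionPair(cid, tid, label, split))

    if row_errors:
        raise DataFormatError(f"{path}: {len(row_errors)} malformed row(s): " + "; ".join(row_errors))
    return DTIDataset(compounds=compounds, targets=targets, pairs=pairs)


def write_dti_table(dataset: DTIDataset, path: str | Path) -> None:
    """Write a dataset in the canonical TSV dialect (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(REQUIRED_DTI_COLUMNS) + ["split"])
        for p in dataset.pairs:
            c = dataset.compounds[p.compound_id]
            t = dataset.targets[p.target_id]
            writer.writerow([c.compound_id, c.smiles or "", t.target_id, t.sequence, p.label, p.split])


# ---------------------------------------------------------------------------
# DUD-E-style decoy directories
# ---------------------------------------------------------------------------


def _read_smiles_lines(path: Path, class_label: str) -> list[CompoundRecord]:
    """Read a DUD-E ``.ism``-style file: one ``SMILES [whitespace] id`` per line."""
    records = []
    with path.open() as fh:
        for i, line in enumerate(fh):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
            records.append(CompoundRecord(compound_id=cid, name=cid, smiles=smiles, class_label=class_label))
    return records


def read_decoy_directory(path: str | Path) -> list[DecoySet]:
    """Read a directory with one sub-directory per target holding actives/decoys.

    Each sub-directory must contain a file whose name starts with ``actives``
    and one starting with ``decoys`` (``.ism``/``.smi``/``.txt``).  Targets with
    an empty decoy pool are excluded with a warning: they cannot seed triplets.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"decoy directory not found: {path}")
    sets: list[DecoySet] = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        actives: list[CompoundRecord] = []
        decoys: list[CompoundRecord] = []
        for f in sorted(sub.iterdir()):
            if f.name.startswith("actives"):
                actives.extend(_read_smiles_lines(f, "active"))
            elif f.name.startswith("decoys"):
                decoys.extend(_read_smiles_lines(f, "decoy"))
        if not decoys:
            logger.warning("target %s has no decoys; excluded from triplet construction", sub.name)
            continue
        logger.info("target %s: %d actives, %d decoys", sub.name, len(actives), len(decoys))
        sets.append(DecoySet(target_id=sub.name, actives=actives, decoys=decoys))
    return sets


# ---------------------------------------------------------------------------
# Compound tables and FASTA targets
# ---------------------------------------------------------------------------


def read_compound_table(
    path: str | Path,
    id_column: str = "compound_id",
    name_column: str = "name",
    smiles_column: str = "smiles",
    class_column: str | None = None,
) -> list[CompoundRecord]:
    """Read a delimited compound table (id, name, SMILES, optional class label).

    Records whose SMILES is missing or unparsable are kept but flagged invalid
    (e.g. protein-like entries in natural-product catalogues); downstream
    featurization skips them.  Duplicate ids raise :class:`DataFormatError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        header_line = fh.readline()
        delim = _sniff_delimiter(header_line)
        columns = [c.strip() for c in header_line.rstrip("\n").split(delim)]
        for col in (id_column, name_column, smiles_column):
            if col not in columns:
                raise DataFormatError(f"{path}: missing required column {col!r}")
        reader = csv.DictReader(fh, fieldnames=columns, delimiter=delim)
        records: list[CompoundRecord] = []
        seen: set[str] = set()
        n_invalid = 0
        for row in reader:
            cid = row[id_column].strip()
            if cid in seen:
                raise DataFormatError(f"{path}: duplicate compound_id {cid!r}")
            seen.add(cid)
            label = "unknown"
            if class_column is not None and row.get(class_column):
                label = row[class_column].strip()
            rec = CompoundRecord(
                compound_id=cid,
                name=row[name_column].strip(),
                smiles=(row[smiles_column] or "").strip() or None,
                class_label=label,
            )
            if not rec.valid:
                n_invalid += 1
            records.append(rec)
    if n_invalid:
        logger.warning("%s: %d record(s) without a parsable SMILES (excluded from featurization)", path, n_invalid)
    return records


def read_fasta_targets(path: str | Path) -> list[TargetRecord]:
    """Read protein targets from a FASTA file; the record id doubles as gene symbol."""
    return [
        TargetRecord(target_id=rec.id, gene_symbol=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta_targets(targets: Iterable[TargetRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in targets:
            fh.write(f">{t.target_id}\n{t.sequence}\n")


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

# Valid SMILES units that stay valid under linear concatenation (no open
# branches, terminal atoms can accept one more bond).
_MOTIF_FRAGMENTS = (
    "c1ccccc1",
    "C1CCCCC1",
    "CC(=O)N",
    "CCOCC",
    "CCSCC",
    "c1ccncc1",
)
# Tag fragments encode a compound's sequence-motif assignment in its own
# structure (distinct halogen/ring signatures), so the assignment is visible
# to the fingerprint and the planted rule is recoverable from features alone.
_TAG_FRAGMENTS = (
    "CC(Cl)",
    "CC(Br)",
    "CC(I)",
    "CC(F)",
    "C1CC1",
    "c1ccoc1",
)
_FILLER_FRAGMENTS = ("C", "CC", "CO", "CN", "CCC")
_MOTIF_COPIES = 5  # planted sequence motifs repeat, like real binding motifs


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic dataset before label noise."""

    target_fragment: dict[str, str]
    compound_motif: dict[str, str]
    truth: dict[str, int] = field(default_factory=dict)  # "cid|tid" -> 0/1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def generate_synthetic_dti(
    spec: SyntheticSpec,
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> tuple[DTIDataset, SyntheticTruth]:
    """Generate a seeded DTI dataset with planted joint motif structure.

    Each target is assigned one chemical fragment motif and each compound one
    sequence motif.  A pair is truly positive iff the compound's SMILES carries
    the target's fragment AND the target's sequence carries the compound's
    motif; observed labels flip the truth with probability ``noise_rate``.
    Carrier probabilities are both sqrt(positive_rate) so the expected positive
    fraction equals ``positive_rate``.  Identical spec and seed give identical
    output.
    """
    rng = random.Random(spec.seed)
    q = spec.positive_rate ** 0.5
    n_kinds = len(_MOTIF_FRAGMENTS)

    # Distinct random peptides: planted interaction motifs plus per-fragment
    # tag peptides that make a target's required fragment visible in sequence.
    peptides: set[str] = set()
    while len(peptides) < 2 * n_kinds:
        peptides.add("".join(rng.choice(AMINO_ACIDS) for _ in range(spec.motif_length)))
    peptide_list = sorted(peptides)
    rng.shuffle(peptide_list)
    motif_pool = peptide_list[:n_kinds]
    tag_peptides = peptide_list[n_kinds:]

    # Targets: assigned fragment (encoded by its tag peptide), sequence with
    # ~q-probability planted motifs, each repeated for a detectable footprint.
    targets: dict[str, TargetRecord] = {}
    target_fragment: dict[str, str] = {}
    target_motifs: dict[str, set[str]] = {}
    for i in range(spec.n_targets):
        tid = f"T{i:04d}"
        frag_idx = i % n_kinds
        carried = set()
        planted = [tag_peptides[frag_idx]] * _MOTIF_COPIES
        for motif in motif_pool:
            if rng.random() < q:
                planted.extend([motif] * _MOTIF_COPIES)
                carried.add(motif)
        # interleave intact motif copies with random filler segments so no
        # planted occurrence is ever clobbered by another insertion
        segments = list(planted)
        for _ in range(len(planted) + 3):
            segments.append("".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(2, 6))))
        rng.shuffle(segments)
        targets[tid] = TargetRecord(target_id=tid, gene_symbol=tid, sequence="".join(segments))
        target_fragment[tid] = _MOTIF_FRAGMENTS[frag_idx]
        target_motifs[tid] = carried

    # Compounds: assigned motif (encoded by its tag fragment), SMILES
    # concatenated from carried motif fragments + tag + filler.
    compounds: dict[str, CompoundRecord] = {}
    compound_motif: dict[str, str] = {}
    compound_frags: dict[str, set[str]] = {}
    for j in range(spec.n_compounds):
        cid = f"C{j:04d}"
        motif_idx = j % n_kinds
        motif = motif_pool[motif_idx]
        carried = {f for f in _MOTIF_FRAGMENTS if rng.random() < q}
        units = sorted(carried) + [_TAG_FRAGMENTS[motif_idx]]
        units += [rng.choice(_FILLER_FRAGMENTS) for _ in range(rng.randint(1, 2))]
        rng.shuffle(units)
        smiles = "".join(units)
        rec = CompoundRecord(compound_id=cid, name=cid, smiles=smiles, class_label="unknown")
        if not rec.valid:  # concatenation rule guarantees validity
            raise AssertionError(f"synthetic SMILES failed to parse: {smiles}")
        compounds[cid] = rec
        compound_motif[cid] = motif
        compound_frags[cid] = carried

    truth = SyntheticTruth(target_fragment=target_fragment, compound_motif=compound_motif)
    pairs: list[InteractionPair] = []
    keys: list[tuple[str, str, int]] = []
    for cid in compounds:
        for tid in targets:
            pos = int(
                target_fragment[tid] in compound_frags[cid]
                and compound_motif[cid] in target_motifs[tid]
            )
            truth.truth[f"{cid}|{tid}"] = pos
            label = pos
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                label = 1 - label
            keys.append((cid, tid, label))

    n_pos = sum(1 for *_k, lab in keys if lab == 1)
    if n_pos == 0 or n_pos == len(keys):
        raise ValueError(
            "positive_rate unreachable under this motif assignment; "
            "increase n_targets/n_compounds or adjust positive_rate"
        )

    # Seeded 70/15/15 split over shuffled pairs.
    order = list(range(len(keys)))
    rng.shuffle(order)
    n = len(order)
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    split_of = {}
    for rank, idx in enumerate(order):
        split_of[idx] = "train" if rank < n_train else "validation" if rank < n_train + n_val else "test"
    for idx, (cid, tid, label) in enumerate(keys):
        pairs.append(InteractionPair(cid, tid, label, split_of[idx]))

    return DTIDataset(compounds=compounds, targets=targets, pairs=pairs), truth


def decoy_sets_from_truth(
    dataset: DTIDataset, truth: SyntheticTruth, max_decoys: int = 60, seed: int = 0
) -> list[DecoySet]:
    """Derive DUD-E-style per-target active/decoy pools from a synthetic truth table."""
    rng = random.Random(seed)
    sets = []
    for tid in dataset.targets:
        actives = [dataset.compounds[cid] for cid in dataset.compounds if truth.truth[f"{cid}|{tid}"] == 1]
        negatives = [dataset.compounds[cid] for cid in dataset.compounds if truth.truth[f"{cid}|{tid}"] == 0]
        if not actives or not negatives:
            continue
        decoys = rng.sample(negatives, min(max_decoys, len(negatives)))
        sets.append(DecoySet(target_id=tid, actives=actives, decoys=decoys))
    return sets
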