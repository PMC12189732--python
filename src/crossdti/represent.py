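"""Latent extraction, 2-D structure-preserving projection and distance ranking.

Projected latents can take arbitrary signs, so cosine similarity is not a
meaningful affinity proxy here; instead the latent cloud of one target plus
candidate compounds is mapped to two dimensions with a neighbor-embedding
method that balances local and global structure (UMAP), and the plain
Euclidean distance from the target's 2-D point to each compound's point ranks
the predicted interaction strength — smaller distance, stronger predicted
interaction.  The target itself heads every ranking at distance 0.00.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .featurize import FeatureSet
from .model import ModelState, project


@dataclass
class LatentMatrix:
    entity_ids: list[str]
    matrix: np.ndarray
    modalities: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != len(self.entity_ids) or len(self.modalities) != len(self.entity_ids):
            raise ValueError("row count must equal entity count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("latent matrix has non-finite entries")


@dataclass
class Projection2D:
    entity_ids: list[str]
    coords: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)
    modalities: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.entity_ids), 2):
            raise ValueError("coords must be (n_entities, 2)")

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["entity_id", "x", "y", "modality"])
            mods = self.modalities or ["?"] * len(self.entity_ids)
            for eid, (x, y), m in zip(self.entity_ids, self.coords, mods):
                writer.writerow([eid, repr(float(x)), repr(float(y)), m])


@dataclass
class RankingRow:
    distance: float  # rounded to 2 decimals for display
    name: str
    class_label: str


@dataclass
class RankingTable:
    target_id: str
    rows: list[RankingRow]

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["euclidean_distance", "compound_name", "class_label"])
            for r in self.rows:
                writer.writerow([f"{r.distance:.2f}", r.name, r.class_label])


def extract_latents(state: ModelState, entities: Sequence[tuple[str, str]], features: FeatureSet) -> LatentMatrix:
    """Project entities (id, modality) through their modality's stack, in order."""
    ids, mods, rows = [], [], []
    for eid, modality in entities:
        emb = getattr(features, modality)[eid]
        rows.append(project(emb.vector[None, :], state, modality)[0])
        ids.append(eid)
        mods.append(modality)
    return LatentMatrix(entity_ids=ids, matrix=np.stack(rows), modalities=mods)


def project_2d(latents: LatentMatrix, seed: int = 0, n_neighbors: int = 10) -> Projection2D:
    """Seeded 2-D neighbor embedding of the latent matrix (UMAP).

    The target must be projected jointly with its compounds in a single run;
    distances across separate projections are not comparable.
    """
    n = latents.matrix.shape[0]
    if n < 8:
        raise ValueError("need at least 8 entities for a 2-D projection; got "
                         f"{n} — reduce n_neighbors or add entities")
    n_neighbors = min(n_neighbors, n - 1)
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=seed, n_jobs=1)
        coords = reducer.fit_transform(latents.matrix)
    return Projection2D(
        entity_ids=list(latents.entity_ids),
        coords=np.asarray(coords, dtype=np.float64),
        seed=seed,
        params={"method": "umap", "n_neighbors": n_neighbors, "min_dist": reducer.min_dist},
        modalities=list(latents.modalities),
    )


def rank_by_distance(
    projection: Projection2D,
    target_id: str,
    compound_ids: Sequence[str],
    names: Mapping[str, str] | None = None,
    class_labels: Mapping[str, str] | None = None,
) -> RankingTable:
    """Rank compounds by 2-D Euclidean distance from the target, ascending.

    The first row is the target itself at distance 0.00.  Sorting uses full
    precision with lexicographic tie-breaks on the name; displayed distances
    are rounded to two decimals.
    """
    pos = {eid: i for i, eid in enumerate(projection.entity_ids)}
    if target_id not in pos:
        raise KeyError(f"target {target_id!r} not in projection")
    missing = [c for c in compound_ids if c not in pos]
    if missing:
        raise KeyError(f"compounds not in projection: {missing}")
    names = names or {}
    class_labels = class_labels or {}
    t_xy = projection.coords[pos[target_id]]
    entries = []
    for cid in compound_ids:
        d = float(np.linalg.norm(projection.coords[pos[cid]] - t_xy))
        entries.append((d, names.get(cid, cid), class_labels.get(cid, "unknown")))
    entries.sort(key=lambda e: (e[0], e[1]))
    rows = [RankingRow(0.00, names.get(target_id, target_id), "target")]
    rows.extend(RankingRow(round(d, 2), name, lab) for d, name, lab in entries)
    return RankingTable(target_id=target_id, rows=rows)


def distance_distributions(
    table: RankingTable, grouping: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Partition a ranking's distances by group (the target row is excluded).

    ``grouping`` maps compound name -> group label and must cover every
    compound in the table.  Suitable for violin-plot export and for
    :func:`crossdti.evaluate.compare_groups`.
    """
    groups: dict[str, list[float]] = {}
    for row in table.rows[1:]:
        if row.name not in grouping:
            raise KeyError(f"compound {row.name!r} missing from grouping")
        groups.setdefault(grouping[row.name], []).append(row.distance)
    return {g: np.array(v) for g, v in groups.items()}


def write_distance_long_csv(groups: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Long-format (group, distance) CSV, one row per compound."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "distance"])
        for g in sorted(groups):
            for d in groups[g]:
                writer.writerow([g, repr(float(d))])
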