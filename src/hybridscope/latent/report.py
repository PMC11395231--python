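"""UMAP projection and responsive-vs-resistant separation reporting.

The separation statistic is the silhouette score of the phase labels in
the full 64-d latent space; the 2-d UMAP projection is used only for
visualization (projection artifacts would otherwise leak into the
statistic).  The feature table carries the interpretable per-crop
measurements that accompany the embedding: normalized CK/CD45/DAPI mean
expression and cell area in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from ..errors import DataError
from ..segment import CellRecord
from .crops import Crop, estimate_area_px
from .vae import EmbeddingSet


@dataclass
class SeparationReport:
    """Phenotype-separation summary for labeled embeddings."""

    silhouette: float
    degenerate: bool
    n_per_class: dict[str, int]
    class_feature_means: dict[str, dict[str, float]]
    directions: dict[str, bool] = field(default_factory=dict)


def embed_umap(
    embeddings: np.ndarray | EmbeddingSet,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
) -> np.ndarray:
    """2-d UMAP coordinates for an embedding matrix (deterministic by seed).

    When given an :class:`EmbeddingSet`, the coordinates are also stored
    on it.
    """
    import umap

    eset = embeddings if isinstance(embeddings, EmbeddingSet) else None
    matrix = embeddings.matrix if eset is not None else np.asarray(embeddings)
    if matrix.shape[0] < n_neighbors + 1:
        raise DataError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, got {matrix.shape[0]}"
        )
    reducer = umap.UMAP(
        n_neighbors=n_neighbors, min_dist=min_dist, n_components=2, random_state=seed
    )
    coords = np.asarray(reducer.fit_transform(matrix), dtype=np.float64)
    if eset is not None:
        eset.umap_coords = coords
    return coords


def feature_table(
    crops: Sequence[Crop], records: Sequence[CellRecord] | None = None
) -> pd.DataFrame:
    """Interpretable per-crop features: channel means, area, phase.

    Channel means are taken from the (normalized) crop tensors; the area
    comes from the matching segmentation record when provided, else from
    a foreground-pixel estimate on the crop itself.
    """
    by_id = {r.cell_id: r for r in records} if records else {}
    rows = []
    for crop in crops:
        means = crop.tensor.mean(axis=(0, 1))
        rec = by_id.get(crop.provenance[1])
        rows.append(
            {
                "sample_id": crop.provenance[0],
                "cell_id": crop.provenance[1],
                "phase": crop.phase,
                "mean_ck": float(means[0]),
                "mean_cd45": float(means[1]),
                "mean_dapi": float(means[2]),
                "area_px": rec.area_px if rec is not None else estimate_area_px(crop),
            }
        )
    return pd.DataFrame(rows)


def phenotype_report(
    embedding_set: EmbeddingSet, min_per_class: int = 5
) -> SeparationReport:
    """Quantify responsive-vs-resistant separation in latent space.

    Requires at least two phase classes with ``min_per_class`` members
    each.  Identical embeddings across all crops are reported as
    degenerate (silhouette 0) rather than an error.  Direction flags
    record whether resistant crops show higher CK and responsive crops
    higher CD45, the expected phenotype contrast.
    """
    labels = np.asarray(embedding_set.labels)
    classes, counts = np.unique(labels, return_counts=True)
    eligible = classes[counts >= min_per_class]
    if eligible.size < 2:
        raise DataError(
            f"need >= 2 classes with >= {min_per_class} crops each, got "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    keep = np.isin(labels, eligible)
    matrix = embedding_set.matrix[keep]
    kept_labels = labels[keep]

    degenerate = bool(np.allclose(matrix, matrix[0]))
    silhouette = 0.0 if degenerate else float(silhouette_score(matrix, kept_labels))

    features = embedding_set.feature_table
    class_means: dict[str, dict[str, float]] = {}
    directions: dict[str, bool] = {}
    if features is not None:
        cols = ["mean_ck", "mean_cd45", "mean_dapi", "area_px"]
        grouped = features.groupby("phase")[cols].mean()
        class_means = {
            phase: {c: float(v) for c, v in row.items()}
            for phase, row in grouped.iterrows()
        }
        if {"responsive", "resistant"} <= set(class_means):
            res, resp = class_means["resistant"], class_means["responsive"]
            directions = {
                "ck_higher_in_resistant": res["mean_ck"] > resp["mean_ck"],
                "cd45_higher_in_responsive": resp["mean_cd45"] > res["mean_cd45"],
            }
    return SeparationReport(
        silhouette=silhouette,
        degenerate=degenerate,
        n_per_class={str(c): int(n) for c, n in zip(classes, counts)},
        class_feature_means=class_means,
        directions=directions,
    )
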