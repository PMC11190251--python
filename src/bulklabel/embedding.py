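"""Two-dimensional embedding of patch features, nearest-neighbor retrieval,
and the k-NN purity score used to track how well the embedding separates
classes.

UMAP is the production projection (patches with similar learned features land
close together, so same-class objects cluster and can be lassoed in bulk);
PCA is a fast, fully deterministic alternative used where bit-stable geometry
matters more than manifold structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .representation import ModelState, compute_features

__all__ = ["EmbeddingPoint", "embed_2d", "retrieve_similar", "knn_purity",
           "coordinates_table"]


@dataclass(frozen=True)
class EmbeddingPoint:
    """One patch's position in the 2-D embedding."""

    image_id: str
    instance_id: int
    x: float
    y: float
    iteration: int = 0


def embed_2d(features: np.ndarray, method: str = "umap", seed: int = 0,
             n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """Project an (n, d) feature matrix to (n, 2) coordinates.

    ``method="umap"`` is the standard manifold projection; ``method="pca"``
    is an exact, deterministic linear alternative.  Both are deterministic
    given ``seed``.  Requires n >= 2 finite feature rows.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("embedding requires at least 2 feature rows")
    if not np.isfinite(x).all():
        raise ValueError("features must be finite")
    if method == "pca":
        k = min(2, x.shape[1])
        coords = PCA(n_components=k, svd_solver="full",
                     random_state=seed).fit_transform(x)
        if k < 2:  # 1-D feature space: pad a zero column
            coords = np.column_stack([coords, np.zeros(len(coords))])
        return coords
    if method == "umap":
        import umap  # deferred: numba JIT makes this import expensive

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, x.shape[0] - 1),
            min_dist=min_dist,
            random_state=seed,
        )
        return np.asarray(reducer.fit_transform(x), dtype=np.float64)
    raise ValueError(f"unknown embedding method {method!r}")


def retrieve_similar(query_patch: np.ndarray, state: ModelState,
                     features: np.ndarray, object_refs, k: int) -> list:
    """Content-based image retrieval: the ``k`` indexed objects whose
    features are nearest (Euclidean) to the query patch's features.

    Ties are broken by object ref; ``k > n`` returns all ``n`` objects in
    order.  The search is exact.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    features = np.asarray(features, dtype=np.float64)
    refs = list(object_refs)
    if features.shape[0] == 0 or not refs:
        raise ValueError("retrieval index is empty")
    q = compute_features(state, [query_patch])[0]
    dist = np.linalg.norm(features - q, axis=1)
    order = sorted(range(len(refs)), key=lambda i: (dist[i], refs[i]))
    return [refs[i] for i in order[:k]]


def knn_purity(points: np.ndarray, labels, k: int) -> float:
    """Mean fraction of each labeled point's k nearest labeled neighbors
    that share its label — a proxy for class separation.

    Works on 2-D coordinates or full feature matrices; unlabeled entries
    (``None``) are ignored.  Requires at least k+1 labeled points.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    points = np.asarray(points, dtype=np.float64)
    labels = list(labels)
    keep = [i for i, l in enumerate(labels) if l is not None]
    if len(keep) < k + 1:
        raise ValueError(f"need at least {k + 1} labeled points, got {len(keep)}")
    x = points[keep]
    y = np.asarray([labels[i] for i in keep])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    fractions = np.empty(len(keep))
    for i, row in enumerate(idx):
        neigh = [j for j in row if j != i][:k]
        fractions[i] = np.mean(y[neigh] == y[i])
    return float(fractions.mean())


def coordinates_table(points: list[EmbeddingPoint]) -> pd.DataFrame:
    """Export embedding points as ``image_id,instance_id,x,y,iteration``."""
    return pd.DataFrame(
        [(p.image_id, p.instance_id, p.x, p.y, p.iteration) for p in points],
        columns=["image_id", "instance_id", "x", "y", "iteration"],
    )
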