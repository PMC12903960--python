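"""ddG-aware embedding-landscape analysis.

Projects per-record mutation-site embedding vectors to 2-D (t-SNE),
clusters the projection with DBSCAN — eps set to the median distance to
the 15th nearest neighbor, min_samples fixed at 15 — and characterizes
each cluster by its ddG statistics, selecting representative clusters
spread evenly across the mean-ddG range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE

from .errors import ConfigurationError, ShapeError


@dataclass
class ClusterProfile:
    """ddG summary of one density cluster (noise points carry id -1 and
    are never profiled)."""

    cluster_id: int
    member_indices: list[int]
    mean_ddg: float
    ddg_range: tuple[float, float]
    size: int


def kth_nn_median_eps(points: np.ndarray, k: int = 15) -> float:
    """Median over points of the Euclidean distance to the k-th nearest
    *other* point (the DBSCAN eps heuristic)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ShapeError("points must be an N x d array")
    n = len(points)
    if n <= k:
        raise ShapeError(f"need more than k={k} points, got {n}")
    dist = squareform(pdist(points))
    kth = np.sort(dist, axis=1)[:, k]  # column 0 is self-distance 0
    return float(np.median(kth))


def cluster(points: np.ndarray, eps: float, min_samples: int = 15) -> np.ndarray:
    """Density-based cluster labels (noise = -1)."""
    if eps <= 0:
        raise ConfigurationError(f"eps must be positive, got {eps}")
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        np.asarray(points, dtype=float)
    )


def profile_clusters(
    labels: np.ndarray,
    ddg: np.ndarray,
    n_representatives: int = 3,
) -> tuple[list[ClusterProfile], list[int]]:
    """Per-cluster ddG profiles plus representative cluster ids.

    Representatives are the clusters at evenly spaced ranks of the
    mean-ddG ordering, giving broad coverage of the ddG range.
    """
    labels = np.asarray(labels)
    ddg = np.asarray(ddg, dtype=float)
    if labels.shape != ddg.shape:
        raise ShapeError("labels and ddg must be aligned")
    if not 3 <= n_representatives <= 5:
        raise ConfigurationError("n_representatives must be between 3 and 5")

    profiles = []
    for cid in sorted(set(labels) - {-1}):
        members = np.flatnonzero(labels == cid)
        vals = ddg[members]
        profiles.append(
            ClusterProfile(
                cluster_id=int(cid),
                member_indices=[int(i) for i in members],
                mean_ddg=float(vals.mean()),
                ddg_range=(float(vals.min()), float(vals.max())),
                size=int(members.size),
            )
        )
    if not profiles:
        warnings.warn("all points labeled noise; no clusters to profile")
        return [], []

    ranked = sorted(profiles, key=lambda p: p.mean_ddg)
    m = min(n_representatives, len(ranked))
    if m == 1:
        picks = [0]
    else:
        picks = sorted({round(i * (len(ranked) - 1) / (m - 1)) for i in range(m)})
    representatives = [ranked[i].cluster_id for i in picks]
    return profiles, representatives


def tsne_project(
    vectors: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
) -> tuple[np.ndarray, dict]:
    """2-D t-SNE projection; returns (coords, metadata with the parameters
    used).  Perplexity is clipped below the sample count as required."""
    vectors = np.asarray(vectors, dtype=float)
    perplexity = min(perplexity, max(2.0, (len(vectors) - 1) / 3.0))
    coords = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(vectors)
    meta = {"method": "tsne", "seed": seed, "perplexity": float(perplexity)}
    return coords, meta


def analyze_embeddings(
    vectors: np.ndarray,
    ddg: np.ndarray,
    seed: int = 0,
    k_nn: int = 15,
    min_samples: int = 15,
    n_representatives: int = 3,
) -> dict:
    """Full pipeline: project, pick eps, cluster, profile."""
    coords, meta = tsne_project(vectors, seed=seed)
    eps = kth_nn_median_eps(coords, k=k_nn)
    labels = cluster(coords, eps, min_samples=min_samples)
    profiles, reps = profile_clusters(labels, ddg, n_representatives)
    return {
        "projection": meta,
        "eps": eps,
        "n_clusters": len(profiles),
        "n_noise": int(np.sum(labels == -1)),
        "labels": [int(l) for l in labels],
        "representatives": reps,
        "clusters": [
            {
                "cluster_id": p.cluster_id,
                "size": p.size,
                "mean_ddg": p.mean_ddg,
                "ddg_range": list(p.ddg_range),
            }
            for p in profiles
        ],
    }
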