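"""Site clustering and image-subset sampling for the elicitation design.

To show each expert a small panel of images spanning the range of habitat
present, observation sites are grouped on mixed-type features — ordinal
vegetation height (1-5) and density (1-4), distance to water, FPC and the
presence/absence record — using the Gower dissimilarity and agglomerative
hierarchical clustering, then one site is drawn uniformly from each cluster.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["gower_distance", "cluster_sites", "sample_image_subset"]


def gower_distance(features: pd.DataFrame) -> np.ndarray:
    """Gower dissimilarity matrix over a mixed-type feature table.

    Binary columns (exactly two distinct values, {0, 1}) contribute a simple
    mismatch; every other numeric column (continuous or ordinal treated as
    interval-scaled) contributes its range-normalized absolute difference.
    The result is the mean contribution over retained variables, a symmetric
    matrix with zero diagonal and entries in [0, 1].  Constant columns carry
    no information and are dropped with a warning.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 rows to compute dissimilarities")
    contrib = []
    dropped = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        rng = np.ptp(x)
        if rng == 0:
            dropped.append(col)
            continue
        diff = np.abs(x[:, None] - x[None, :])
        values = np.unique(x)
        if len(values) == 2 and set(values) <= {0.0, 1.0}:
            contrib.append((diff > 0).astype(float))  # simple mismatch
        else:
            contrib.append(diff / rng)
    if dropped:
        warnings.warn(f"dropping constant feature(s) {dropped}", stacklevel=2)
    if not contrib:
        raise ValueError("all features constant: Gower distance undefined")
    return np.mean(contrib, axis=0)


def cluster_sites(
    dist: np.ndarray, n_clusters: int, method: str = "complete"
) -> np.ndarray:
    """Cut an agglomerative hierarchy of the distance matrix at ``n_clusters``.

    ``method`` selects the linkage: ``"complete"`` (default) or ``"average"``
    (UPGMA).  Labels are integers 1..n_clusters.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("dist must be a symmetric matrix with zero diagonal")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if method not in ("complete", "average"):
        raise ValueError("linkage method must be 'complete' or 'average'")
    Z = linkage(squareform(dist, checks=False), method=method)
    return fcluster(Z, t=n_clusters, criterion="maxclust")


def sample_image_subset(labels: np.ndarray, seed: int) -> np.ndarray:
    """Draw one site uniformly at random from each cluster.

    Returns row indices into ``labels``, ordered by cluster label;
    reproducible under ``seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    picks = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        picks.append(int(rng.choice(members)))
    return np.array(picks)
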