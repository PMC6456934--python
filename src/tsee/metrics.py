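"""Structure-preservation metrics for low-dimensional embeddings.

The in-group proportion (IGP) of a group is the fraction of its members
whose nearest neighbor in the embedding carries the same group label; IGP2
relaxes the match to the same *or adjacent* time stage (|rank difference|
<= 1), which is the appropriate score when cell types straddle consecutive
collection stages. The misplaced-cell diagnostic flags cells whose nearest
neighbor lies at least two stages away — exactly the complement of IGP2 on
each stage. A weighted mean of per-stage IGPs (weights proportional to
stage sizes) summarizes a whole embedding in one number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core import pairwise_sq_distances

__all__ = [
    "MetricReport",
    "nearest_neighbor_index",
    "igp",
    "igp2",
    "weighted_mean_igp",
    "pearson_correlation",
    "misplaced_cells",
    "stage_centroid_linkage",
    "evaluate_embedding",
]


@dataclass
class MetricReport:
    igp_per_group: Dict[int, float]
    igp2_per_group: Dict[int, float]
    weighted_mean_igp: float
    misplaced_mask: np.ndarray
    pcc_time: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "igp_per_group": {str(k): v for k, v in self.igp_per_group.items()},
            "igp2_per_group": {str(k): v for k, v in self.igp2_per_group.items()},
            "weighted_mean_igp": self.weighted_mean_igp,
            "pcc_time": self.pcc_time,
            "n_misplaced": int(self.misplaced_mask.sum()),
            "misplaced_fraction": float(self.misplaced_mask.mean()),
        }


def nearest_neighbor_index(x: np.ndarray) -> np.ndarray:
    """Index of each point's closest other point (Euclidean), ties to the
    smallest index. Duplicate points are valid mutual nearest neighbors."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("at least two points are required")
    d2 = pairwise_sq_distances(x)
    np.fill_diagonal(d2, np.inf)
    return d2.argmin(axis=1)  # argmin returns the first (smallest) index on ties


def _as_labels(labels, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("one label per point is required")
    return labels

def _as_stage_index(labels, n: int) -> np.ndarray:
    labels = _as_labels(labels, n)
    if not np.issubdtype(labels.dtype, np.integer):
        as_int = labels.astype(int, copy=False) if np.issubdtype(labels.dtype, np.number) else None
        if as_int is None or not np.array_equal(as_int, labels):
            raise ValueError("ordinal stage indices (consecutive integers) are required")
        labels = as_int
    stages = np.unique(labels)
    if not np.array_equal(stages, np.arange(stages.min(), stages.max() + 1)):
        raise ValueError("stage indices must be consecutive integers")
    return labels


def igp(x: np.ndarray, group: np.ndarray) -> Dict:
    """Per-group in-group proportion.

    IGP(u) = #{j : label(j) = label(NN(j)) = u} / #{j : label(j) = u}.
    Singleton groups score 0 (their nearest neighbor is necessarily outside).
    """
    x = np.asarray(x, dtype=float)
    labels = _as_labels(group, x.shape[0])
    nn = nearest_neighbor_index(x)
    same = labels == labels[nn]
    return {
        u: float(same[labels == u].mean())
        for u in np.unique(labels)
    }


def igp2(x: np.ndarray, stage_index: np.ndarray) -> Dict[int, float]:
    """Per-stage in-group proportion relaxed to adjacent stages.

    IGP2(u) counts a cell as well-placed when its nearest neighbor's stage
    rank differs by at most 1; consequently IGP2(u) >= IGP(u) for every u.
    """
    x = np.asarray(x, dtype=float)
    labels = _as_stage_index(stage_index, x.shape[0])
    nn = nearest_neighbor_index(x)
    near = np.abs(labels - labels[nn]) <= 1
    return {
        int(u): float(near[labels == u].mean())
        for u in np.unique(labels)
    }


def weighted_mean_igp(per_group: Dict, group_sizes: Dict) -> float:
    """Size-weighted mean of per-group scores: sum_u score(u) m_u / N."""
    if not per_group:
        raise ValueError("empty score map")
    if set(per_group) != set(group_sizes):
        raise ValueError("score and size maps must share the same groups")
    total = sum(group_sizes.values())
    return float(sum(per_group[u] * group_sizes[u] for u in per_group) / total)


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; errors on zero-variance input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def misplaced_cells(x: np.ndarray, stage_index: np.ndarray) -> np.ndarray:
    """Boolean mask of cells whose nearest neighbor is >= 2 stages away.

    Within each stage the flagged fraction equals exactly 1 - IGP2(stage).
    """
    x = np.asarray(x, dtype=float)
    labels = _as_stage_index(stage_index, x.shape[0])
    nn = nearest_neighbor_index(x)
    return np.abs(labels - labels[nn]) >= 2


def stage_centroid_linkage(x: np.ndarray, stage_index: np.ndarray):
    """Complete-linkage agglomeration of per-stage centroids.

    Returns ``(stages, Z)`` where ``stages`` lists the stage labels in the
    order used as leaves and ``Z`` is the scipy linkage matrix (merge order
    and heights) of complete linkage on Euclidean centroid distances. A
    single stage yields an empty merge table.
    """
    x = np.asarray(x, dtype=float)
    labels = _as_stage_index(stage_index, x.shape[0])
    stages = np.unique(labels)
    centroids = np.vstack([x[labels == u].mean(axis=0) for u in stages])
    if len(stages) < 2:
        return stages, np.empty((0, 4))
    return stages, linkage(centroids, method="complete", metric="euclidean")


def evaluate_embedding(
    x: np.ndarray,
    stage_index: np.ndarray,
    pseudotime: Optional[np.ndarray] = None,
    reference_time: Optional[np.ndarray] = None,
) -> MetricReport:
    """Bundle the per-stage metrics of an embedding into one report.

    When both ``pseudotime`` (e.g. from an external trajectory method, or a
    synthetic ground truth) and ``reference_time`` (experimental stage time)
    are given, their Pearson correlation measures global temporal structure.
    """
    x = np.asarray(x, dtype=float)
    labels = _as_stage_index(stage_index, x.shape[0])
    per_igp = igp(x, labels)
    per_igp2 = igp2(x, labels)
    sizes = {int(u): int((labels == u).sum()) for u in np.unique(labels)}
    wmean = weighted_mean_igp({int(k): v for k, v in per_igp.items()}, sizes)
    mask = misplaced_cells(x, labels)
    pcc = None
    if pseudotime is not None and reference_time is not None:
        pcc = pearson_correlation(pseudotime, reference_time)
    return MetricReport(
        igp_per_group={int(k): v for k, v in per_igp.items()},
        igp2_per_group=per_igp2,
        weighted_mean_igp=wmean,
        misplaced_mask=mask,
        pcc_time=pcc,
    )
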