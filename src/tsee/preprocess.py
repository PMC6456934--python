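"""Four-step preprocessing of raw time-series expression matrices.

Order is fixed: (1) keep the most variable genes by the Z-score of their
per-gene variance, (2) global min-max normalization of the whole matrix to
[0, 1], (3) PCA reduction keeping the smallest number of components whose
cumulative explained variance reaches a target (or an explicit count),
(4) global min-max normalization of the component scores. Stage times are
independently mapped affinely to [0, 1] (earliest stage 0, latest 1).

No library-size normalization or log transform is applied here: whether the
input is raw counts or already-normalized values is the caller's choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .dataset import TimeSeriesDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "select_variable_genes",
    "minmax_normalize",
    "normalize_times",
    "pca_reduce",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    n_variable_genes: int = 1000
    pca_variance_target: Optional[float] = 0.95
    pca_components: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_variable_genes < 1:
            raise ValueError("n_variable_genes must be positive")
        if (self.pca_variance_target is None) == (self.pca_components is None):
            raise ValueError(
                "exactly one of pca_variance_target / pca_components must be set"
            )
        if self.pca_variance_target is not None and not (0 < self.pca_variance_target <= 1):
            raise ValueError("pca_variance_target must lie in (0, 1]")
        if self.pca_components is not None and self.pca_components < 1:
            raise ValueError("pca_components must be positive")


def select_variable_genes(raw: np.ndarray, n_keep: int) -> np.ndarray:
    """Indices (ascending) of the ``n_keep`` genes with the largest variance Z-scores.

    Variances are computed per gene across cells, then Z-scored
    ((v - mean(v)) / sd(v)); since Z-scoring is monotone this equals a
    top-variance selection, with ties broken toward the lower gene index.
    If every gene has identical variance the Z-scores are undefined and the
    first ``n_keep`` genes are returned with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    n_genes = raw.shape[1]
    if not (1 <= n_keep <= n_genes):
        raise ValueError(f"n_keep must be in 1..{n_genes}, got {n_keep}")
    variances = raw.var(axis=0)
    sd = variances.std()
    if sd == 0:
        logger.warning(
            "all %d genes have identical variance; Z-scores undefined, "
            "keeping the first %d genes", n_genes, n_keep,
        )
        return np.arange(n_keep)
    z = (variances - variances.mean()) / sd
    # stable sort on -z: equal scores keep ascending gene-index order
    order = np.argsort(-z, kind="stable")
    return np.sort(order[:n_keep])


def minmax_normalize(m: np.ndarray) -> np.ndarray:
    """Whole-matrix min-max scaling: subtract the global minimum, divide by the
    maximum of the shifted matrix. Output spans exactly [0, 1]."""
    m = np.asarray(m, dtype=float)
    lo = m.min()
    shifted = m - lo
    hi = shifted.max()
    if hi == 0:
        raise ValueError("degenerate matrix: all values identical")
    return shifted / hi


def normalize_times(stage_times: Sequence[float]) -> np.ndarray:
    """Affine map of stage times onto [0, 1] (min -> 0, max -> 1).

    Interval ratios are preserved. A single distinct time yields all zeros
    with a warning (temporal repulsion then has no effect).
    """
    t = np.asarray(stage_times, dtype=float)
    lo, hi = t.min(), t.max()
    if hi == lo:
        logger.warning("single time stage: normalized times all zero, "
                       "temporal repulsion will be inert")
        return np.zeros_like(t)
    return (t - lo) / (hi - lo)


def pca_reduce(m: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Principal-component scores keeping enough components for the variance target.

    Columns are centered; K is the smallest count whose cumulative explained
    variance reaches ``pca_variance_target``, or the explicit
    ``pca_components`` (clamped to min(N-1, G) with a warning). Each
    component is sign-flipped so the largest-magnitude loading entry is
    positive, making the output deterministic.
    """
    m = np.asarray(m, dtype=float)
    n, g = m.shape
    if n < 2:
        raise ValueError("at least two rows are required for PCA")
    max_k = min(n - 1, g)
    pca = PCA(n_components=min(max_k, g), svd_solver="full")
    scores = pca.fit_transform(m)
    if config.pca_components is not None:
        k = config.pca_components
        if k > max_k:
            logger.warning("pca_components=%d exceeds rank bound %d; clamping", k, max_k)
            k = max_k
    else:
        cumulative = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cumulative, config.pca_variance_target - 1e-12) + 1)
        k = min(k, max_k)
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return scores[:, :k]


def preprocess_pipeline(
    raw: np.ndarray,
    stage_labels: Sequence[float],
    config: Optional[PreprocessConfig] = None,
    cell_ids: Optional[list] = None,
) -> TimeSeriesDataset:
    """Run the full preprocessing chain and assemble a TimeSeriesDataset.

    ``stage_labels`` are per-cell raw collection times (e.g. hours
    post-fertilization); stages are their sorted unique values, ranked
    1..n, and the normalized per-cell stage time comes from
    :func:`normalize_times` applied to those per-cell values.
    """
    if config is None:
        config = PreprocessConfig()
    raw = np.asarray(raw, dtype=float)
    times = np.asarray(stage_labels, dtype=float)
    if times.shape != (raw.shape[0],):
        raise ValueError("stage_labels must align with the matrix rows")

    n_keep = min(config.n_variable_genes, raw.shape[1])
    if n_keep < config.n_variable_genes:
        logger.info("only %d genes available; keeping all", raw.shape[1])
    kept = select_variable_genes(raw, n_keep)
    selected = raw[:, kept]
    normalized = minmax_normalize(selected)
    scores = pca_reduce(normalized, config)
    expression = minmax_normalize(scores)

    unique_times = np.unique(times)
    stage_index = np.searchsorted(unique_times, times) + 1
    stage_time = normalize_times(times)

    return TimeSeriesDataset(
        expression=expression,
        stage_index=stage_index,
        stage_time=stage_time,
        cell_ids=list(cell_ids) if cell_ids is not None else [],
        feature_ids=[f"PC{j + 1}" for j in range(expression.shape[1])],
    )
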