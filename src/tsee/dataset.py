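"""Container for a preprocessed time-series expression matrix.

Cells are rows everywhere in this package. Each cell carries two pieces of
temporal metadata: an ordinal stage index (1..n, the rank of its collection
stage) and a normalized stage time in [0, 1] (earliest stage -> 0, latest
stage -> 1). The stage time is the quantity that enters the temporal
repulsion of the embedding energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeriesDataset:
    """Preprocessed expression profiles with per-cell stage annotations.

    Parameters
    ----------
    expression
        (N, D) float array of preprocessed values, expected in [0, 1].
    stage_index
        (N,) int array of 1-based stage ranks; every stage in 1..n occupied.
    stage_time
        (N,) float array of normalized collection times in [0, 1]; constant
        within a stage and increasing with stage_index.
    cell_ids, feature_ids
        Row / column identifiers.
    """

    expression: np.ndarray
    stage_index: np.ndarray
    stage_time: np.ndarray
    cell_ids: list = field(default_factory=list)
    feature_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        self.stage_index = np.asarray(self.stage_index, dtype=int)
        self.stage_time = np.asarray(self.stage_time, dtype=float)
        n, d = self.expression.shape
        if n < 2 or d < 1:
            raise ValueError(f"expression must be at least 2x1, got {n}x{d}")
        if self.stage_index.shape != (n,) or self.stage_time.shape != (n,):
            raise ValueError("stage_index/stage_time must have one entry per cell")
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i:05d}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"feature_{j:05d}" for j in range(d)]
        if len(self.cell_ids) != n or len(self.feature_ids) != d:
            raise ValueError("id vectors do not match matrix shape")
        if self.stage_time.min() < -1e-12 or self.stage_time.max() > 1 + 1e-12:
            raise ValueError("stage_time values must lie in [0, 1]")
        stages = np.unique(self.stage_index)
        if stages.min() < 1 or not np.array_equal(stages, np.arange(1, stages.max() + 1)):
            raise ValueError("stage_index must cover consecutive integers 1..n")
        # stage order must agree with stage time order
        order = np.argsort(self.stage_time, kind="stable")
        if np.any(np.diff(self.stage_index[order]) < 0):
            raise ValueError("stage_index must be non-decreasing in stage_time")

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_features(self) -> int:
        return self.expression.shape[1]

    @property
    def n_stages(self) -> int:
        return int(self.stage_index.max())
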