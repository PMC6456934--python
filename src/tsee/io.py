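"""Readers and writers for expression matrices, labels, embeddings and manifests.

Internal convention: cells are rows. Dense TSV/CSV tables carry feature ids
in the header row and cell ids in the first column. MatrixMarket input
follows the common single-cell convention (genes x cells, with sibling
feature and barcode id files, one id per line) and is transposed on load.
Label files join to the expression matrix by cell id, never by file order.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.io import mmread

from . import __version__
from .core import EmbeddingResult
from .dataset import TimeSeriesDataset


def _repr_float(v) -> str:
    # repr of a Python float is the shortest exact round-trip form
    return repr(float(v))

__all__ = [
    "read_expression",
    "write_expression",
    "read_stage_labels",
    "write_stage_labels",
    "write_embedding",
    "read_embedding",
    "build_manifest",
]

_SEPS = {"dense_tsv": "\t", "dense_csv": ","}


def read_expression(
    path,
    format: str = "dense_tsv",
    features_path=None,
    barcodes_path=None,
    max_entries: int = 200_000_000,
) -> Tuple[np.ndarray, List[str], List[str]]:
    """Load an expression matrix as (cells x genes, cell_ids, feature_ids).

    ``format`` is one of dense_tsv / dense_csv (header = feature ids, first
    column = cell ids) or mtx (MatrixMarket genes x cells, transposed on
    load; sibling id files default to features.tsv / barcodes.tsv next to
    the matrix). ``max_entries`` guards against densifying a matrix too
    large to hold.
    """
    path = Path(path)
    if format in _SEPS:
        try:
            frame = pd.read_csv(path, sep=_SEPS[format], index_col=0,
                                float_precision="round_trip")
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"{path}: malformed table: {exc}") from exc
        matrix = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if np.isnan(matrix).any():
            row = int(np.flatnonzero(np.isnan(matrix).any(axis=1))[0])
            raise ValueError(
                f"{path}: missing/non-numeric value in data line {row + 1} "
                f"(cell {frame.index[row]!r})"
            )
        return matrix, [str(c) for c in frame.index], [str(f) for f in frame.columns]

    if format == "mtx":
        sparse = mmread(path)
        n_genes, n_cells = sparse.shape
        if n_genes * n_cells > max_entries:
            raise ValueError(
                f"{path}: densifying {n_genes}x{n_cells} exceeds the "
                f"{max_entries}-entry budget; raise max_entries to override"
            )
        matrix = np.asarray(sparse.todense(), dtype=float).T  # -> cells x genes
        features_path = Path(features_path) if features_path else path.parent / "features.tsv"
        barcodes_path = Path(barcodes_path) if barcodes_path else path.parent / "barcodes.tsv"
        feature_ids = [ln.split("\t")[0] for ln in _read_id_lines(features_path)]
        cell_ids = [ln.split("\t")[0] for ln in _read_id_lines(barcodes_path)]
        if len(feature_ids) != n_genes:
            raise ValueError(
                f"{features_path}: {len(feature_ids)} ids for {n_genes} matrix rows"
            )
        if len(cell_ids) != n_cells:
            raise ValueError(
                f"{barcodes_path}: {len(cell_ids)} ids for {n_cells} matrix columns"
            )
        return matrix, cell_ids, feature_ids

    raise ValueError(f"unknown expression format {format!r}")


def _read_id_lines(path: Path) -> List[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def write_expression(path, matrix: np.ndarray, cell_ids, feature_ids,
                     format: str = "dense_tsv") -> None:
    """Write a cells x genes table in dense TSV/CSV, repr-faithful floats."""
    if format not in _SEPS:
        raise ValueError(f"unknown expression format {format!r}")
    frame = pd.DataFrame(np.asarray(matrix, dtype=float),
                         index=list(cell_ids), columns=list(feature_ids))
    frame.to_csv(path, sep=_SEPS[format], index_label="cell_id", float_format=_repr_float)


def read_stage_labels(path, cell_ids) -> Tuple[np.ndarray, np.ndarray]:
    """Load per-cell stage times, joined to ``cell_ids`` by id.

    The file is a TSV with columns cell_id and stage_time. Returns the raw
    stage times aligned to ``cell_ids`` and the 1-based stage index assigned
    by the rank of each cell's time among the sorted unique stage times.
    Missing or duplicated ids are reported explicitly.
    """
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"cell_id", "stage_time"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path}: label file must have columns {sorted(required)}")
    table["cell_id"] = table["cell_id"].astype(str)
    dup = table["cell_id"][table["cell_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate cell ids: {dup[:10]}")
    lookup = dict(zip(table["cell_id"], pd.to_numeric(table["stage_time"], errors="coerce")))
    wanted = [str(c) for c in cell_ids]
    missing = [c for c in wanted if c not in lookup]
    if missing:
        raise ValueError(f"{path}: missing cell ids: {missing[:10]}")
    times = np.array([lookup[c] for c in wanted], dtype=float)
    if np.isnan(times).any():
        bad = [wanted[i] for i in np.flatnonzero(np.isnan(times))[:10]]
        raise ValueError(f"{path}: non-numeric stage_time for cells {bad}")
    unique_times = np.unique(times)
    stage_index = np.searchsorted(unique_times, times) + 1
    return times, stage_index


def write_stage_labels(path, cell_ids, stage_times) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "stage_time": np.asarray(stage_times)}).to_csv(
        path, sep="\t", index=False, float_format=_repr_float
    )


def write_embedding(path, result: EmbeddingResult, dataset: TimeSeriesDataset,
                    manifest: Optional[dict] = None) -> None:
    """Write coordinates + stage metadata as TSV; a manifest JSON goes alongside.

    Floats are written via repr, so a read-back reproduces the in-memory
    coordinates bit-for-bit.
    """
    path = Path(path)
    x = result.coordinates
    frame = pd.DataFrame(
        x, index=dataset.cell_ids,
        columns=[f"dim_{j + 1}" for j in range(x.shape[1])],
    )
    frame["stage_time"] = dataset.stage_time
    frame["stage_index"] = dataset.stage_index
    frame.to_csv(path, sep="\t", index_label="cell_id", float_format=_repr_float)
    manifest = dict(manifest or {})
    manifest.setdefault("software_version", __version__)
    manifest.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S%z"))
    manifest.update(
        n_cells=int(x.shape[0]), dim=int(x.shape[1]),
        n_iterations=result.n_iterations, converged=result.converged,
        sigma=result.sigma, final_energy=result.energy_trace[-1],
        config=vars(result.config_used),
    )
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def read_embedding(path) -> Tuple[np.ndarray, List[str], np.ndarray, np.ndarray]:
    """Read back an embedding TSV -> (coordinates, cell_ids, stage_time, stage_index)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    dims = [c for c in frame.columns if c.startswith("dim_")]
    if not dims:
        raise ValueError(f"{path}: no dim_* coordinate columns found")
    coords = frame[dims].to_numpy(dtype=float)
    stage_time = frame["stage_time"].to_numpy(dtype=float)
    stage_index = frame["stage_index"].to_numpy(dtype=int)
    return coords, [str(c) for c in frame.index], stage_time, stage_index


def build_manifest(inputs: dict, config: dict, seed: Optional[int] = None) -> dict:
    """Assemble the run manifest that accompanies every embedding output."""
    return {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "seed": seed,
        "software_version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
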