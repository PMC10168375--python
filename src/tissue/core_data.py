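"""Data containers and file I/O for spatial and dissociated expression data.

Conventions shared by every module in the package:

* matrices are oriented cells x genes;
* spatial expression is used raw (counts or whatever the platform reports) —
  any normalisation of the spatial panel is the caller's responsibility;
* the dissociated (scRNA-seq) reference is filtered, depth-normalised and
  log1p-transformed by :func:`preprocess_reference` before prediction;
* gene names are matched by exact string equality (no case folding) because
  silent case-merging corrupts gene panels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("tissue")

__all__ = [
    "SpatialDataset",
    "ReferenceDataset",
    "PredictionMatrix",
    "load_spatial",
    "write_spatial",
    "load_reference",
    "preprocess_reference",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate {what} id: {dup!r}")
    return ids


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        idx = np.argwhere(~np.isfinite(a))[0]
        raise ValueError(f"non-finite value in {what} at index {tuple(idx)}")


@dataclass
class SpatialDataset:
    """Spatial expression matrix with 2-D cell coordinates.

    Parameters
    ----------
    values
        Nonnegative expression matrix, cells x genes.
    coords
        Cell coordinates, cells x 2.
    cell_ids, gene_ids
        Unique identifiers matching the matrix dimensions.
    labels
        Optional categorical label per cell (cell_id -> label).
    """

    values: np.ndarray
    coords: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.coords.shape != (len(self.cell_ids), 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.cell_ids)} cells x 2"
            )
        _check_finite(self.values, "expression")
        _check_finite(self.coords, "coords")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression for cell {self.cell_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if self.labels is not None:
            missing = [c for c in self.labels if c not in set(self.cell_ids)]
            if missing:
                raise ValueError(f"label for unknown cell {missing[0]!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def label_array(self) -> np.ndarray | None:
        """Labels in cell order, or None when no labels were provided."""
        if self.labels is None:
            return None
        missing = [c for c in self.cell_ids if c not in self.labels]
        if missing:
            raise ValueError(f"cell {missing[0]!r} has no label")
        return np.asarray([self.labels[c] for c in self.cell_ids], dtype=object)

    def subset_genes(self, genes: Sequence[str]) -> "SpatialDataset":
        idx = [self.gene_ids.index(g) for g in genes]
        return SpatialDataset(
            self.values[:, idx],
            self.coords,
            list(self.cell_ids),
            [self.gene_ids[i] for i in idx],
            dict(self.labels) if self.labels is not None else None,
        )

    def subset_cells(self, keep: Sequence[int] | np.ndarray) -> "SpatialDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.cell_ids[i] for i in keep]
        labels = None
        if self.labels is not None:
            labels = {c: self.labels[c] for c in ids if c in self.labels}
        return SpatialDataset(
            self.values[keep], self.coords[keep], ids, list(self.gene_ids), labels
        )


@dataclass
class ReferenceDataset:
    """Dissociated (scRNA-seq) reference matrix, cells x genes."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.gene_ids):
            raise ValueError("reference shape does not match gene_ids")
        if self.cell_ids is not None:
            self.cell_ids = _check_unique(self.cell_ids, "cell")
            if len(self.cell_ids) != self.values.shape[0]:
                raise ValueError("reference shape does not match cell_ids")
        _check_finite(self.values, "reference")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class PredictionMatrix:
    """Predicted expression for a set of genes over the spatial cells.

    Cell ordering always matches the :class:`SpatialDataset` the prediction
    was made for.
    """

    values: np.ndarray
    gene_ids: list[str]
    source: str = "unknown"
    fold_id: np.ndarray | None = None  # per-gene CV fold provenance
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.gene_ids):
            raise ValueError("prediction shape does not match gene_ids")
        _check_finite(self.values, "prediction")
        if self.fold_id is not None:
            self.fold_id = np.asarray(self.fold_id, dtype=int)
            if self.fold_id.shape != (len(self.gene_ids),):
                raise ValueError("fold_id must have one entry per gene")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def _read_expression(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a dense delimited table or MatrixMarket triplets with sidecars.

    For ``X.mtx`` the row (cell) and column (gene) names are read from the
    one-column sidecar files ``X.rows.txt`` and ``X.cols.txt``.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mat = scipy.io.mmread(path)
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        rows = path.with_suffix(".rows.txt")
        cols = path.with_suffix(".cols.txt")
        cell_ids = rows.read_text().split()
        gene_ids = cols.read_text().split()
        if len(cell_ids) != values.shape[0] or len(gene_ids) != values.shape[1]:
            raise ValueError(
                f"matrix {values.shape} does not match sidecars "
                f"({len(cell_ids)} cells, {len(gene_ids)} genes)"
            )
        return values, cell_ids, gene_ids
    df = _read_table(path)
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def load_spatial(
    expr_path: str | Path,
    coords_path: str | Path,
    labels_path: str | Path | None = None,
) -> SpatialDataset:
    """Load a spatial dataset from expression + coordinate (+ label) files.

    Expression may be a dense CSV/TSV (header row of gene ids, first column
    of cell ids) or a MatrixMarket ``.mtx`` with ``.rows.txt``/``.cols.txt``
    sidecars. Coordinates are a delimited table ``(cell_id, x, y)``; every
    expression cell must have coordinates. Labels are ``(cell_id, label)``.
    """
    values, cell_ids, gene_ids = _read_expression(expr_path)
    coords_df = _read_table(coords_path)
    if coords_df.shape[1] < 2:
        raise ValueError("coordinates table must have columns (cell_id, x, y)")
    coords_df.index = coords_df.index.astype(str)
    missing = [c for c in cell_ids if c not in coords_df.index]
    if missing:
        raise ValueError(f"cell {missing[0]!r} has no coordinates")
    coords = coords_df.loc[cell_ids].iloc[:, :2].to_numpy(dtype=float)
    labels = None
    if labels_path is not None:
        lab_df = _read_table(labels_path)
        lab_df.index = lab_df.index.astype(str)
        labels = {str(c): str(v) for c, v in lab_df.iloc[:, 0].items()}
    return SpatialDataset(values, coords, cell_ids, gene_ids, labels)


def write_spatial(data: SpatialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a SpatialDataset as TSV tables; inverse of :func:`load_spatial`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "coords": out_dir / "coords.tsv",
    }
    pd.DataFrame(data.values, index=data.cell_ids, columns=data.gene_ids).to_csv(
        paths["expression"], sep="\t", index_label="cell_id"
    )
    pd.DataFrame(data.coords, index=data.cell_ids, columns=["x", "y"]).to_csv(
        paths["coords"], sep="\t", index_label="cell_id"
    )
    if data.labels is not None:
        paths["labels"] = out_dir / "labels.tsv"
        pd.Series(data.labels, name="label").rename_axis("cell_id").to_csv(
            paths["labels"], sep="\t"
        )
    return paths


def load_reference(expr_path: str | Path) -> ReferenceDataset:
    """Load a reference expression matrix (same formats as load_spatial)."""
    values, cell_ids, gene_ids = _read_expression(expr_path)
    return ReferenceDataset(values, gene_ids, cell_ids)


def preprocess_reference(
    ref: ReferenceDataset,
    min_frac: float = 0.01,
    target_sum: float | str = "median",
) -> ReferenceDataset:
    """Filter, depth-normalise and log-transform a raw reference matrix.

    Genes with nonzero expression in fewer than ``ceil(min_frac * n_cells)``
    cells are removed; cells with zero total counts are dropped with a
    warning; the remaining counts are rescaled so every cell's total equals
    ``target_sum`` (the median of per-cell totals when ``"median"``); finally
    ``log(1 + x)`` is applied.
    """
    import anndata
    import scanpy as sc

    values = np.asarray(ref.values, dtype=float)
    if np.any(values < 0):
        raise ValueError("reference counts must be nonnegative")
    n_cells = values.shape[0]
    min_cells = int(np.ceil(min_frac * n_cells))
    keep_genes = (values > 0).sum(axis=0) >= min_cells
    if not keep_genes.any():
        raise ValueError("all genes removed by the expression-fraction filter")
    values = values[:, keep_genes]
    gene_ids = [g for g, k in zip(ref.gene_ids, keep_genes) if k]

    totals = values.sum(axis=1)
    keep_cells = totals > 0
    if not keep_cells.all():
        warnings.warn(
            f"excluding {int((~keep_cells).sum())} reference cells "
            "with zero total counts"
        )
        values = values[keep_cells]
    cell_ids = None
    if ref.cell_ids is not None:
        cell_ids = [c for c, k in zip(ref.cell_ids, keep_cells) if k]

    adata = anndata.AnnData(values.copy())
    sc.pp.normalize_total(
        adata, target_sum=None if target_sum == "median" else float(target_sum)
    )
    sc.pp.log1p(adata)
    return ReferenceDataset(np.asarray(adata.X, dtype=float), gene_ids, cell_ids)
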