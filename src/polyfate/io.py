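"""Expression-matrix containers and readers/writers.

The canonical in-memory object is :class:`ExpressionMatrix`: a cells x genes
array of non-negative RPKM-like values with ordered, unique gene and cell
identifiers.  Matrices can be read from delimited text (one header row of
gene ids, one leading column of cell ids) or from a MatrixMarket triplet
with companion one-id-per-line gene/cell files.

Expression values arrive on the raw scale; modeling operates on
``log2(x + 1)`` values (the usual single-cell convention) via
:func:`log_transform`.  Death-probability labeling, by contrast, uses the
raw scale — see :mod:`polyfate.labeling`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .errors import ConfigError, FormatError, MissingGeneError, StateError

Orientation = Literal["cells_by_genes", "genes_by_cells"]
Scale = Literal["raw", "log"]


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with identifiers.

    Parameters
    ----------
    values
        2-D float array, rows = cells, columns = genes.  Non-negative on the
        raw scale (RPKM-like units); dimensionless after the log transform.
    gene_ids, cell_ids
        Ordered unique identifiers matching the matrix dimensions.
    donor_group
        Optional per-cell group label (e.g. ``"healthy"`` / ``"T2D"``).
    scale
        ``"raw"`` or ``"log"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    donor_group: np.ndarray | None = None
    scale: Scale = "raw"
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(f"duplicate {name} ids: {dupes[:5]}")
        if self.donor_group is not None:
            self.donor_group = np.asarray(self.donor_group)
            if self.donor_group.shape != (n_cells,):
                raise FormatError("donor_group length must equal the cell count")
        if self.scale == "raw" and self.values.size and self.values.min() < 0:
            raise ValueError("raw-scale expression values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise MissingGeneError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression of one gene across all cells (a view when possible)."""
        return self.values[:, self.gene_index(gene)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return replace(
            self, values=self.values[:, idx], gene_ids=list(genes)
        )

    def subset_cells(self, index: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        donor = self.donor_group[index] if self.donor_group is not None else None
        return ExpressionMatrix(
            values=self.values[index],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
            donor_group=donor,
            scale=self.scale,
        )


def read_expression_matrix(
    path: str | Path,
    orientation: Orientation = "cells_by_genes",
    *,
    gene_file: str | Path | None = None,
    cell_file: str | Path | None = None,
    group_column: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or a MatrixMarket triplet.

    Delimited text must carry one header row and one leading identifier
    column; ``orientation`` states which axis the file's rows represent, and
    ``genes_by_cells`` input is transposed to the canonical cells x genes
    layout.  A ``.mtx`` path requires ``gene_file`` and ``cell_file``
    (one identifier per line).  ``group_column`` names an optional column of
    donor-group labels in delimited input.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if gene_file is None or cell_file is None:
            raise FormatError("MTX input requires gene_file and cell_file")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        gene_ids = _read_id_file(gene_file)
        cell_ids = _read_id_file(cell_file)
        if orientation == "genes_by_cells":
            mat = mat.T
        return ExpressionMatrix(mat, gene_ids, cell_ids, scale="raw")

    sep = "," if path.suffix == ".csv" else "\t"
    with open(path) as fh:
        header = [h for h in fh.readline().rstrip("\n").split(sep) if h]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        kind = "cell" if orientation == "genes_by_cells" else "gene"
        raise FormatError(f"{path}: duplicate {kind} ids in header: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.hasnans or df.columns.hasnans:
        raise FormatError(f"{path}: missing identifiers in header or index")
    group = None
    if group_column is not None:
        if group_column not in df.columns:
            raise FormatError(f"{path}: no column {group_column!r}")
        group = df.pop(group_column).to_numpy()
    if not df.map(lambda v: isinstance(v, (int, float))).to_numpy().all():
        raise FormatError(f"{path}: non-numeric expression values")
    values = df.to_numpy(dtype=float)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "genes_by_cells":
        values = values.T
        gene_ids, cell_ids = row_ids, col_ids
        if group is not None:
            raise FormatError("group_column requires cells_by_genes orientation")
    else:
        gene_ids, cell_ids = col_ids, row_ids
    if np.isnan(values).any():
        raise FormatError(f"{path}: missing expression values")
    try:
        return ExpressionMatrix(
            values, gene_ids, cell_ids, donor_group=group, scale="raw"
        )
    except ValueError as exc:  # negative values: keep the ValueError contract
        raise ValueError(f"{path}: {exc}") from None


def _read_id_file(path: str | Path) -> list[str]:
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate identifiers")
    return ids


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, group_column: str | None = None
) -> None:
    """Write cells x genes delimited text (TSV unless the suffix is .csv)."""
    path = Path(path)
    df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
    if group_column is not None and m.donor_group is not None:
        df[group_column] = m.donor_group
    df.to_csv(path, sep="," if path.suffix == ".csv" else "\t")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix with values mapped elementwise to ``log2(x + 1)``.

    The offset keeps zeros at zero and the transform monotone; shape and
    identifiers are preserved.  Applying it twice is refused.
    """
    if m.scale == "log":
        raise StateError("matrix is already log-scaled")
    return replace(m, values=np.log2(m.values + 1.0), scale="log")


def ensure_log(m: ExpressionMatrix) -> ExpressionMatrix:
    """Log-transform raw input; pass log-scale input through unchanged."""
    return m if m.scale == "log" else log_transform(m)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    try:
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot parse config ({exc})") from None
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg
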