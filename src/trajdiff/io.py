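"""Dataset container and readers/writers.

The central object is :class:`MultiSampleDataset`: a genes x cells matrix of
log-scale, library-size-normalized expression values, a cells x D embedding in
which all samples have been harmonized upstream, a cell -> sample assignment,
and a samples x (V+1) numeric design matrix whose first column is an
intercept of ones.  Cells are columns of the expression matrix throughout the
package.

Expression can be read from MatrixMarket triplets (with gene/cell id sidecar
files), dense CSV, or HDF5; metadata and design tables are TSV.  In
``backing_mode="disk"`` the HDF5 expression matrix stays on disk and genes are
streamed one at a time.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger("trajdiff")

#: p-values below the double-precision floor are serialized as this token.
PVALUE_FLOOR_LABEL = "<2.22e-308"
_TINY = np.finfo(float).tiny


class AlignmentError(ValueError):
    """Cell/sample identifiers do not line up across inputs."""


class IntegrityError(ValueError):
    """Duplicate ids, missing design rows, or missing values."""


@dataclass
class MultiSampleDataset:
    """Aligned multi-sample single-cell dataset.

    Parameters
    ----------
    expression
        genes x cells matrix of normalized log-scale values.  Either an
        in-memory ndarray or an ``h5py.Dataset`` when disk-backed.
    gene_ids, cell_ids
        Ordered identifiers for rows/columns of ``expression``.
    sample_of_cell
        Sample label per cell, aligned with ``cell_ids``.
    embedding
        cells x D numeric matrix (harmonized low-dimensional coordinates).
    sample_design
        samples x (V+1) numeric DataFrame indexed by sample label; the first
        column is an all-ones intercept.
    """

    expression: np.ndarray | h5py.Dataset
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_of_cell: np.ndarray
    embedding: np.ndarray
    sample_design: pd.DataFrame
    backing: str = "memory"
    _h5file: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.expression.shape
        if len(self.gene_ids) != n_genes:
            raise AlignmentError(
                f"{len(self.gene_ids)} gene ids for {n_genes} expression rows"
            )
        if len(self.cell_ids) != n_cells:
            raise AlignmentError(
                f"{len(self.cell_ids)} cell ids for {n_cells} expression columns"
            )
        if self.embedding.shape[0] != n_cells:
            raise AlignmentError(
                f"embedding has {self.embedding.shape[0]} rows for {n_cells} cells"
            )
        if len(self.sample_of_cell) != n_cells:
            raise AlignmentError("sample_of_cell length mismatch")
        if len(set(self.cell_ids)) != n_cells:
            raise IntegrityError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("duplicate gene ids")
        missing = set(self.sample_of_cell) - set(self.sample_design.index)
        if missing:
            raise IntegrityError(f"samples missing from design: {sorted(missing)}")
        design = self.sample_design.to_numpy()
        if design.dtype.kind not in "fiu":
            raise IntegrityError("design matrix must be numeric")
        if not np.allclose(design[:, 0], 1.0):
            raise IntegrityError("first design column must be an intercept of ones")
        if self.backing == "memory":
            if not np.all(np.isfinite(self.expression)):
                raise IntegrityError("missing/non-finite expression values")
            if np.all(~np.isfinite(self.expression), axis=1).any():
                raise IntegrityError("gene with all-missing values")
        if not np.all(np.isfinite(self.embedding)):
            raise IntegrityError("missing values in embedding")

    # -- convenience ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expression.shape[1]

    @property
    def samples(self) -> list:
        return list(self.sample_design.index)

    def gene_index(self, gene) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise KeyError(f"unknown gene: {gene}")
        return int(idx[0])

    def gene_values(self, gene) -> np.ndarray:
        """Expression vector of one gene across all cells (streams from disk)."""
        row = self.expression[self.gene_index(gene), :]
        return np.asarray(row, dtype=float)

    def to_memory(self) -> "MultiSampleDataset":
        if self.backing == "memory":
            return self
        expr = np.asarray(self.expression[...], dtype=float)
        return MultiSampleDataset(
            expr, self.gene_ids, self.cell_ids, self.sample_of_cell,
            self.embedding, self.sample_design, backing="memory",
        )

    def cells_of_sample(self, sample) -> np.ndarray:
        return np.flatnonzero(self.sample_of_cell == sample)


def expand_design(design: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical covariates to dummy columns (reference level =
    lexicographically first) and prepend an intercept column of ones.

    An existing all-ones "intercept" column is recognized and not duplicated.
    """
    design = design.copy()
    if "intercept" in design.columns:
        if not np.allclose(design["intercept"].astype(float), 1.0):
            raise IntegrityError("'intercept' column must be all ones")
        design = design.drop(columns=["intercept"])
    cols = {}
    for name in design.columns:
        col = design[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols[f"{name}_{lev}"] = (col.astype(str) == lev).astype(float)
    out = pd.DataFrame(cols, index=design.index)
    out.insert(0, "intercept", 1.0)
    return out


def _read_expression(path: str):
    """Read genes x cells expression from MTX/CSV/HDF5.

    MTX expects ``<stem>.mtx`` plus ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` sidecars (one id per line).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mtx":
        mat = np.asarray(mmread(path).todense(), dtype=float)
        stem = os.path.splitext(path)[0]
        genes = np.loadtxt(stem + ".genes.txt", dtype=str, ndmin=1)
        cells = np.loadtxt(stem + ".cells.txt", dtype=str, ndmin=1)
        return mat, genes, cells, None
    if ext in (".csv",):
        df = pd.read_csv(path, index_col=0)
        return df.to_numpy(dtype=float), df.index.to_numpy(str), df.columns.to_numpy(str), None
    if ext in (".h5", ".hdf5"):
        f = h5py.File(path, "r")
        genes = f["gene_ids"].asstr()[...]
        cells = f["cell_ids"].asstr()[...]
        return f["expression"], genes, cells, f
    raise ValueError(f"unsupported expression format: {path}")


def load_dataset(
    expression_path: str,
    metadata_path: str,
    embedding_path: str,
    design_path: str,
    backing_mode: str = "memory",
) -> MultiSampleDataset:
    """Load and align expression, metadata, embedding and design.

    ``metadata_path`` is a TSV with columns ``cell`` and ``sample``;
    ``embedding_path`` a TSV/CSV with cell ids in the first column;
    ``design_path`` a TSV indexed by sample with covariate columns
    (categoricals are dummy-expanded).  Cells present in the expression matrix
    but absent from metadata are dropped with a logged count.
    """
    expr, genes, cells, h5handle = _read_expression(expression_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"cell", "sample"} <= set(meta.columns):
        raise IntegrityError("metadata must have 'cell' and 'sample' columns")
    if meta["cell"].duplicated().any():
        raise IntegrityError("duplicate cell ids in metadata")
    meta = meta.set_index("cell")

    sep = "\t" if embedding_path.endswith((".tsv", ".txt")) else ","
    emb = pd.read_csv(embedding_path, sep=sep, index_col=0)

    keep = np.array([c in meta.index and c in emb.index for c in cells])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d cells absent from metadata/embedding", n_dropped)

    design_raw = pd.read_csv(design_path, sep="\t", index_col=0)
    for col in design_raw.columns:
        coerced = pd.to_numeric(design_raw[col], errors="coerce")
        if coerced.notna().all():
            design_raw[col] = coerced
        elif pd.api.types.is_numeric_dtype(design_raw[col]):
            raise IntegrityError(f"non-numeric entries in design column {col}")
    design = expand_design(design_raw)

    cells_kept = cells[keep]
    if backing_mode == "disk" and h5handle is not None and keep.all():
        expression = expr  # leave on disk, stream gene-by-gene
        backing = "disk"
    else:
        expression = np.asarray(expr[...] if h5handle is not None else expr, float)
        expression = expression[:, keep]
        backing = "memory"
        if h5handle is not None:
            h5handle.close()
            h5handle = None
    if not np.all(np.isfinite(np.asarray(expression[:, :1], float))):
        raise IntegrityError("missing values in expression")

    samples = meta.loc[cells_kept, "sample"].to_numpy()
    missing = set(samples) - set(design.index)
    if missing:
        raise IntegrityError(f"samples missing from design: {sorted(missing)}")

    return MultiSampleDataset(
        expression=expression,
        gene_ids=genes,
        cell_ids=cells_kept,
        sample_of_cell=samples,
        embedding=emb.loc[cells_kept].to_numpy(dtype=float),
        sample_design=design.loc[sorted(set(samples))],
        backing=backing,
        _h5file=h5handle,
    )


def save_expression_h5(dataset: MultiSampleDataset, path: str) -> None:
    """Write expression + ids to a single HDF5 file (one 2-D dataset)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("expression", data=np.asarray(dataset.expression[...], float),
                         chunks=(1, dataset.n_cells))
        st = h5py.string_dtype()
        f.create_dataset("gene_ids", data=[str(g) for g in dataset.gene_ids],
                         dtype=st)
        f.create_dataset("cell_ids", data=[str(c) for c in dataset.cell_ids],
                         dtype=st)


def _format_p(x) -> str:
    if isinstance(x, str):
        return x
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if 0 <= x < _TINY:
        return PVALUE_FLOOR_LABEL
    return repr(float(x))


def write_result_table(results: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV with stable column order.

    Columns named ``p_value``/``p_*`` have values below the double-precision
    floor rendered as ``<2.22e-308``; everything else round-trips to 1e-12.
    """
    df = results.copy()
    preferred = [c for c in ("id", "gene", "branch", "statistic", "llr",
                             "p_value", "fdr", "category") if c in df.columns]
    rest = [c for c in df.columns if c not in preferred]
    df = df[preferred + rest]
    for col in df.columns:
        if col == "p_value" or col.startswith("p_"):
            df[col] = [_format_p(x) for x in df[col]]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_result_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col == "p_value" or col.startswith("p_"):
            df[col] = [
                0.0 if x == PVALUE_FLOOR_LABEL else float(x)
                for x in df[col].replace("NA", np.nan)
            ]
    return df
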