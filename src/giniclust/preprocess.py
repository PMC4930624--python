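"""Expression-matrix container, loaders, and quality filters.

The pipeline operates on a genes-by-cells matrix of nonnegative expression
values.  Three modalities are distinguished: ``umi`` (deduplicated transcript
counts from droplet protocols), ``read`` (raw read counts), and ``qpcr_log2``
(log2-scale expression derived from qPCR Ct values).  The modality tag decides
downstream behaviour — e.g. the bidirectional Gini index and the correlation
distance are only meaningful for qPCR data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

MODALITIES = ("umi", "read", "qpcr_log2")

__all__ = [
    "ExpressionMatrix",
    "load_matrix",
    "save_matrix",
    "ct_to_expression",
    "filter_genes",
    "filter_cells",
]


class MatrixFormatError(ValueError):
    """Raised when an input file cannot be parsed into an expression matrix."""


@dataclass
class ExpressionMatrix:
    """Genes-by-cells expression matrix with names and a modality tag.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array of nonnegative expression values.
    gene_names, cell_names
        Unique identifiers matching the two axes.
    modality
        One of ``umi``, ``read``, ``qpcr_log2``.
    """

    values: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    cell_names: list[str] = field(default_factory=list)
    modality: str = "umi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_names = [str(c) for c in self.cell_names]
        n_genes, n_cells = self.values.shape
        if len(self.gene_names) != n_genes:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n_genes} matrix rows"
            )
        if len(self.cell_names) != n_cells:
            raise ValueError(
                f"{len(self.cell_names)} cell names for {n_cells} matrix columns"
            )
        _check_unique(self.gene_names, "gene")
        _check_unique(self.cell_names, "cell")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains non-finite entries")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative entries")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    # -- convenience -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, modality: str = "umi") -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns), modality)

    def subset_genes(self, keep: np.ndarray | Sequence[str]) -> "ExpressionMatrix":
        idx = _as_index(keep, self.gene_names, "gene")
        return replace(
            self,
            values=self.values[idx, :],
            gene_names=[self.gene_names[i] for i in idx],
            cell_names=list(self.cell_names),
        )

    def subset_cells(self, keep: np.ndarray | Sequence[str]) -> "ExpressionMatrix":
        idx = _as_index(keep, self.cell_names, "cell")
        return replace(
            self,
            values=self.values[:, idx],
            gene_names=list(self.gene_names),
            cell_names=[self.cell_names[i] for i in idx],
        )


def _check_unique(names: Iterable[str], axis: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate {axis} name: {name!r}")
        seen.add(name)


def _as_index(keep, names: list[str], axis: str) -> np.ndarray:
    keep = np.asarray(keep)
    if keep.dtype == bool:
        if keep.size != len(names):
            raise ValueError(f"boolean {axis} mask has wrong length")
        return np.flatnonzero(keep)
    if keep.dtype.kind in "iu":
        return keep
    lookup = {n: i for i, n in enumerate(names)}
    try:
        return np.array([lookup[str(k)] for k in keep], dtype=int)
    except KeyError as err:
        raise KeyError(f"unknown {axis} name: {err.args[0]!r}") from None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_names(path: Path, axis: str) -> list[str]:
    names = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not names:
        raise MatrixFormatError(f"{axis} name file {path} is empty")
    return names


def load_matrix(
    path: str | Path,
    format: str = "csv",
    modality: str = "umi",
    *,
    genes_file: str | Path | None = None,
    cells_file: str | Path | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or MatrixMarket triplet format.

    CSV/TSV layout: genes as rows, first column gene names, header row cell
    names.  MatrixMarket requires sidecar ``genes_file`` / ``cells_file``
    (one name per line, rows = genes).  The loader never guesses orientation;
    pass ``transpose=True`` if the file stores cells as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as err:  # pragma: no cover - pandas message passthrough
            raise MatrixFormatError(f"cannot parse {path}: {err}") from err
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise MatrixFormatError(f"non-numeric column(s) in {path}: {bad}")
        if transpose:
            df = df.T
        values = df.to_numpy(dtype=float)
        gene_names, cell_names = list(df.index), list(df.columns)
    elif format == "mtx_triplet":
        if genes_file is None or cells_file is None:
            raise ValueError("mtx_triplet format requires genes_file and cells_file")
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as err:
            raise MatrixFormatError(f"cannot parse {path}: {err}") from err
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if transpose:
            values = values.T
        gene_names = _read_names(Path(genes_file), "gene")
        cell_names = _read_names(Path(cells_file), "cell")
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(values, gene_names, cell_names, modality)


def save_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    format: str = "csv",
    *,
    genes_file: str | Path | None = None,
    cells_file: str | Path | None = None,
) -> None:
    """Write a matrix in the same layouts :func:`load_matrix` reads."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        m.to_dataframe().to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        if genes_file is None or cells_file is None:
            raise ValueError("mtx_triplet format requires genes_file and cells_file")
        values = m.values
        if np.allclose(values, np.round(values)):
            sparse = scipy.sparse.coo_matrix(values.astype(np.int64))
            scipy.io.mmwrite(str(path), sparse, field="integer")
        else:
            scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(values))
        Path(genes_file).write_text("\n".join(m.gene_names) + "\n")
        Path(cells_file).write_text("\n".join(m.cell_names) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Transformations and filters
# ---------------------------------------------------------------------------

def ct_to_expression(
    ct_values: np.ndarray | pd.DataFrame,
    background: float = 28.0,
    gene_names: Sequence[str] | None = None,
    cell_names: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Convert qPCR Ct values to log2-scale expression.

    Expression is ``max(background - Ct, 0)``: a Ct at or above the background
    level (default 28 cycles) means no detectable transcript and maps to zero;
    lower Ct means exponentially more template, so ``background - Ct``
    approximates log2 expression.
    """
    if background <= 0:
        raise ValueError("background must be positive")
    if isinstance(ct_values, pd.DataFrame):
        gene_names = gene_names or list(ct_values.index)
        cell_names = cell_names or list(ct_values.columns)
        ct = ct_values.to_numpy(dtype=float)
    else:
        ct = np.asarray(ct_values, dtype=float)
        if ct.ndim != 2:
            raise ValueError("ct_values must be 2-D (genes x cells)")
        if gene_names is None:
            gene_names = [f"gene{i}" for i in range(ct.shape[0])]
        if cell_names is None:
            cell_names = [f"cell{j}" for j in range(ct.shape[1])]
    expr = np.maximum(background - ct, 0.0)
    return ExpressionMatrix(expr, list(gene_names), list(cell_names), "qpcr_log2")


def filter_genes(m: ExpressionMatrix, min_cells: int = 3) -> ExpressionMatrix:
    """Drop genes expressed (value > 0) in fewer than ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    n_expressing = (m.values > 0).sum(axis=1)
    keep = n_expressing >= min_cells
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return m.subset_genes(keep)


def filter_cells(m: ExpressionMatrix, min_genes: int = 2000) -> ExpressionMatrix:
    """Drop cells expressing (value > 0) fewer than ``min_genes`` genes."""
    if min_genes < 0:
        raise ValueError("min_genes must be nonnegative")
    n_detected = (m.values > 0).sum(axis=0)
    keep = n_detected >= min_genes
    if not keep.any():
        raise ValueError(
            "cell filter removed every cell; lower min_genes "
            f"(max detected genes per cell = {int(n_detected.max(initial=0))})"
        )
    return m.subset_cells(keep)
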