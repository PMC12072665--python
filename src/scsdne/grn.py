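"""Per-cell-type gene regulatory network adjacency.

A cell-type GRN here is a symmetric non-negative gene-gene matrix with a
zero diagonal: the entry W[i, j] is the likelihood of a regulatory
relationship between genes i and j within one cell type, direction
discarded. Two backends produce it:

* ``load_grn`` adapts a precomputed adjacency (e.g. exported by an external
  GRN inference tool) to the analysis gene order;
* ``CoexpressionGRN`` / ``coexpression_grn`` is a self-contained estimator
  based on absolute Spearman correlation with global top-k sparsification.

Either way the raw matrix is passed through ``symmetrize``: entrywise
absolute value, then W[i, j] = W[j, i] = max of the mirror pair, diagonal
forced to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .io import AnnotatedExpression

__all__ = ["CellTypeGRN", "symmetrize", "coexpression_grn", "load_grn", "CoexpressionGRN"]


@dataclass
class CellTypeGRN:
    W: np.ndarray
    cell_type: str = ""
    backend_tag: str = "precomputed"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.ndim != 2 or self.W.shape != (n, n):
            raise ValueError("GRN adjacency must be square")
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("GRN adjacency must be exactly symmetric")
        if (self.W < 0).any():
            raise ValueError("GRN adjacency must be non-negative")
        if np.diagonal(self.W).any():
            raise ValueError("GRN adjacency must have zero diagonal")


def symmetrize(w_raw: np.ndarray, cell_type: str = "", backend_tag: str = "precomputed") -> CellTypeGRN:
    """Abs-then-max symmetrization with zeroed diagonal.

    W[i, j] = W[j, i] = max(|W_raw[i, j]|, |W_raw[j, i]|); self-edges carry
    no meaning for embedding proximity and are removed.
    """
    w_raw = np.asarray(w_raw, dtype=float)
    if w_raw.ndim != 2 or w_raw.shape[0] != w_raw.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {w_raw.shape}")
    if not np.isfinite(w_raw).all():
        raise ValueError("GRN adjacency contains non-finite entries")
    a = np.abs(w_raw)
    W = np.maximum(a, a.T)
    np.fill_diagonal(W, 0.0)
    return CellTypeGRN(W, cell_type=cell_type, backend_tag=backend_tag)


def _spearman_abs(mat: np.ndarray) -> np.ndarray:
    """|Spearman rho| between rows of *mat*; constant rows get 0."""
    ranks = np.apply_along_axis(rankdata, 1, mat)
    sd = ranks.std(axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * mat.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ centered.T) / np.where(denom > 0, denom, 1.0)
    rho[(sd == 0)[:, None] | (sd == 0)[None, :]] = 0.0
    return np.clip(np.abs(rho), 0.0, 1.0)


def coexpression_grn(
    expr: AnnotatedExpression, cell_type: str, top_k_edges: int
) -> CellTypeGRN:
    """Sparse co-expression GRN from absolute Spearman correlation.

    Correlations are computed over cells of *cell_type* only; the
    ``top_k_edges`` strongest undirected edges are kept (ties at the cutoff
    value are all kept, for determinism under permutation) and everything
    else is zeroed.
    """
    cols = expr.cells_of_type(cell_type)
    if cols.size < 3:
        raise ValueError(
            f"need >= 3 cells of type {cell_type!r} for co-expression, got {cols.size}"
        )
    rho = _spearman_abs(expr.matrix[:, cols])
    np.fill_diagonal(rho, 0.0)
    if top_k_edges <= 0:
        rho = np.zeros_like(rho)
    else:
        upper = rho[np.triu_indices_from(rho, k=1)]
        k = min(top_k_edges, upper.size)
        cutoff = np.sort(upper)[-k]
        rho = np.where(rho >= cutoff, rho, 0.0)
    return symmetrize(rho, cell_type=cell_type, backend_tag="coexpression")


class CoexpressionGRN(BaseEstimator):
    """Estimator wrapper for the co-expression GRN backend.

    Parameters
    ----------
    top_k_edges : int
        Number of undirected edges to retain after global sparsification.

    Attributes
    ----------
    adjacency_ : ndarray of shape (n_genes, n_genes)
        Symmetric non-negative adjacency with zero diagonal.
    grn_ : CellTypeGRN
        The full result object including provenance tags.
    """

    def __init__(self, top_k_edges: int = 1000):
        self.top_k_edges = top_k_edges

    def fit(self, expr: AnnotatedExpression, cell_type: str) -> "CoexpressionGRN":
        self.grn_ = coexpression_grn(expr, cell_type, self.top_k_edges)
        self.adjacency_ = self.grn_.W
        return self


def load_grn(path: str | Path, gene_order: list[str]) -> CellTypeGRN:
    """Load a precomputed adjacency and reindex it to *gene_order*.

    Accepted layouts: edge-list TSV with header (gene_i, gene_j, weight);
    square matrix TSV with gene names as index and header; MTX with a
    ``<stem>.genes.txt`` sidecar. Genes absent from the file become zero
    rows/columns (logged); the result passes through ``symmetrize``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        sidecar = path.with_suffix("").with_suffix(".genes.txt")
        if not sidecar.exists():
            sidecar = path.parent / (path.stem + ".genes.txt")
        with open(sidecar) as fh:
            file_genes = [line.strip() for line in fh if line.strip()]
        mat = np.asarray(mmread(path).todense(), dtype=float)
        frame = pd.DataFrame(mat, index=file_genes, columns=file_genes)
    else:
        with open(path) as fh:
            header = [c.strip().lower() for c in fh.readline().rstrip("\n").split("\t")]
        if header[:3] == ["gene_i", "gene_j", "weight"]:
            df = pd.read_csv(path, sep="\t")
            genes = sorted({str(g) for g in df.iloc[:, 0]} | {str(g) for g in df.iloc[:, 1]})
            frame = pd.DataFrame(0.0, index=genes, columns=genes)
            for gi, gj, w in df.itertuples(index=False):
                frame.loc[str(gi), str(gj)] = float(w)
        else:
            frame = pd.read_csv(path, sep="\t", index_col=0)
            frame.columns = [str(c) for c in frame.columns]
            frame.index = [str(i) for i in frame.index]
    overlap = [g for g in gene_order if g in frame.index]
    if not overlap:
        raise ValueError(f"{path}: no genes overlap the analysis gene order")
    missing = [g for g in gene_order if g not in frame.index]
    if missing:
        warnings.warn(
            f"{path}: {len(missing)} gene(s) absent from GRN file, zero-filled: "
            + ", ".join(missing[:5])
            + ("..." if len(missing) > 5 else "")
        )
    full = pd.DataFrame(0.0, index=gene_order, columns=gene_order)
    full.loc[overlap, overlap] = frame.loc[overlap, overlap].to_numpy(dtype=float)
    return symmetrize(full.to_numpy(), backend_tag="precomputed")
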