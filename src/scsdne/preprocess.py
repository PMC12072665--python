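"""Cell QC filtering, library-size normalization, HVG selection, type means.

This is the minimal processing stage the interaction caller needs: it
consumes raw counts with per-cell type labels (annotation itself is an
upstream responsibility) and produces normalized expression restricted to
highly variable genes, plus per-type mean-expression vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AnnotatedExpression

__all__ = [
    "PreprocessConfig",
    "filter_cells",
    "normalize",
    "select_hvg",
    "mean_by_type",
]


@dataclass
class PreprocessConfig:
    """Thresholds for the QC/normalization/HVG stage.

    min_genes_per_cell
        cells with fewer detected (nonzero) genes are removed.
    max_mito_fraction
        cells whose mitochondrial counts exceed this fraction of their
        library are removed; mitochondrial genes are identified by
        ``mito_prefix`` on the gene symbol.
    normalize_scale
        per-cell library size after normalization (counts per ten thousand
        by default), before the log1p transform.
    n_hvg
        number of highly variable genes retained, ranked by dispersion.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.2
    normalize_scale: float = 1e4
    n_hvg: int = 2000
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.n_hvg < 2:
            raise ValueError("n_hvg must be >= 2")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.normalize_scale <= 0:
            raise ValueError("normalize_scale must be positive")


def filter_cells(expr: AnnotatedExpression, cfg: PreprocessConfig) -> AnnotatedExpression:
    """Remove low-quality cells by detected-gene count and mitochondrial load.

    A cell survives iff it detects at least ``min_genes_per_cell`` genes and
    its mitochondrial count fraction is at most ``max_mito_fraction``. The
    gene set is unchanged.
    """
    detected = (expr.matrix > 0).sum(axis=0)
    mito_rows = np.array(
        [g.upper().startswith(cfg.mito_prefix.upper()) for g in expr.gene_names]
    )
    totals = expr.matrix.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, expr.matrix[mito_rows, :].sum(axis=0) / np.maximum(totals, 1e-300), 0.0
        )
    keep = (detected >= cfg.min_genes_per_cell) & (mito_frac <= cfg.max_mito_fraction)
    if not keep.any():
        raise ValueError(
            "all cells removed by QC thresholds; relax min_genes_per_cell "
            f"(={cfg.min_genes_per_cell}) or max_mito_fraction (={cfg.max_mito_fraction})"
        )
    return expr.subset_cells(np.flatnonzero(keep))


def normalize(expr: AnnotatedExpression, cfg: PreprocessConfig) -> AnnotatedExpression:
    """Library-size normalize then log-transform: x -> ln(1 + x/total * scale)."""
    totals = expr.matrix.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = ", ".join(expr.cell_names[i] for i in zero[:5])
        raise ValueError(f"cells with zero total counts (filter first): {names}")
    mat = np.log1p(expr.matrix / totals * cfg.normalize_scale)
    return AnnotatedExpression(
        mat, list(expr.gene_names), list(expr.cell_names), dict(expr.cell_types)
    )


def select_hvg(
    expr: AnnotatedExpression,
    cfg: PreprocessConfig,
    force_include: list[str] | None = None,
) -> list[str]:
    """Top ``n_hvg`` genes by dispersion (variance/mean of normalized values).

    Dispersion uses population variance across all cells; genes with zero
    mean get dispersion 0. Ties break lexicographically by gene name so the
    selection is deterministic. Genes listed in *force_include* (e.g. L-R
    database members) are kept regardless of rank, within the same budget.
    """
    mean = expr.matrix.mean(axis=1)
    var = expr.matrix.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    n = min(cfg.n_hvg, expr.n_genes)
    if cfg.n_hvg > expr.n_genes:
        warnings.warn(
            f"n_hvg={cfg.n_hvg} exceeds gene count {expr.n_genes}; returning all genes"
        )
    # sort by (-dispersion, name): highest dispersion first, ties lexicographic
    ranked = sorted(range(expr.n_genes), key=lambda i: (-disp[i], expr.gene_names[i]))
    chosen = [expr.gene_names[i] for i in ranked[:n]]
    if force_include:
        present = [g for g in force_include if g in set(expr.gene_names)]
        missing_from_top = [g for g in present if g not in set(chosen)]
        if missing_from_top:
            keep = [g for g in chosen if g not in set(missing_from_top)]
            chosen = keep[: max(0, n - len(missing_from_top))] + missing_from_top
            # restore dispersion-rank order over the final set
            rank = {expr.gene_names[i]: r for r, i in enumerate(ranked)}
            chosen = sorted(chosen, key=lambda g: rank[g])
    return chosen


def mean_by_type(
    expr: AnnotatedExpression, type_a: str, type_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene arithmetic mean expression for each of two cell types.

    Returns ``(u_A, u_B)`` on the expression object's gene ordering.
    """
    cols_a = expr.cells_of_type(type_a)
    cols_b = expr.cells_of_type(type_b)
    u_a = expr.matrix[:, cols_a].mean(axis=1)
    u_b = expr.matrix[:, cols_b].mean(axis=1)
    return u_a, u_b
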