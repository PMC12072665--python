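"""Crosstalk scores between genes of a sender and a receiver cell type.

The score for gene i in sender type A and gene j in receiver type B is a
saturating function of the product of their per-type mean expression levels,

    score(i, j) = u_iA * u_jB / (c + u_iA * u_jB),

where c is the mean of the expression submatrix restricted to cells of the
two types. Scores lie in [0, 1), are zero exactly when the product of means
is zero, and increase monotonically in each mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotatedExpression

__all__ = ["CrosstalkMatrix", "compute_c", "crosstalk_score", "crosstalk_matrix"]


@dataclass
class CrosstalkMatrix:
    """Sender-gene x receiver-gene score matrix on a shared gene order."""

    S: np.ndarray
    c: float
    gene_order: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.gene_order)
        if self.S.shape != (n, n):
            raise ValueError(f"S shape {self.S.shape} does not match {n} genes")
        if self.c <= 0:
            raise ValueError("scaling constant c must be positive")
        if (self.S < 0).any() or (self.S >= 1).any():
            raise ValueError("crosstalk scores must lie in [0, 1)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.gene_order, columns=self.gene_order)

    def dump_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def compute_c(expr: AnnotatedExpression, type_a: str, type_b: str) -> float:
    """Mean of all entries of the expression submatrix over cells of both types."""
    cols = np.concatenate([expr.cells_of_type(type_a), expr.cells_of_type(type_b)])
    sub = expr.matrix[:, cols]
    c = float(sub.mean())
    if c == 0.0:
        raise ValueError("expression submatrix for the two types is all-zero")
    return c


def crosstalk_score(u_ia: float, u_jb: float, c: float) -> float:
    """Score for one gene pair: u_iA*u_jB / (c + u_iA*u_jB)."""
    if c <= 0:
        raise ValueError("c must be positive")
    if u_ia < 0 or u_jb < 0:
        raise ValueError("mean expression levels must be non-negative")
    prod = u_ia * u_jb
    return prod / (c + prod)


def crosstalk_matrix(
    u_a: np.ndarray,
    u_b: np.ndarray,
    c: float,
    gene_order: list[str] | None = None,
) -> CrosstalkMatrix:
    """Entrywise score matrix S[i, j] = score(u_A[i], u_B[j])."""
    u_a = np.asarray(u_a, dtype=float)
    u_b = np.asarray(u_b, dtype=float)
    if u_a.shape != u_b.shape or u_a.ndim != 1:
        raise ValueError(f"u_A and u_B must be 1-D of equal length, got {u_a.shape}, {u_b.shape}")
    if (u_a < 0).any() or (u_b < 0).any():
        raise ValueError("mean expression levels must be non-negative")
    if c <= 0:
        raise ValueError("c must be positive")
    prod = np.outer(u_a, u_b)
    S = prod / (c + prod)
    if gene_order is None:
        gene_order = [f"g{i}" for i in range(u_a.size)]
    return CrosstalkMatrix(S, float(c), list(gene_order))
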