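"""Joint similarity matrix over sender and receiver gene copies.

The 2n x 2n block matrix

    X = [[W_A / mu,  S       ],
         [S.T,       W_B / mu]]

combines the two intracellular GRNs (diagonal blocks) with the
intercellular crosstalk scores (off-diagonal blocks). The scaling factor
mu balances their contributions:

* dense mode:        mu = (sum W_A + sum W_B) / (2 * sum S)
* sparse-aware mode: s = sum of S over the union support of W_A and W_B
                     (positions where either GRN has a non-zero entry),
                     mu = (sum W_A + sum W_B) / (2 s)

Sparse-aware is the default: it weights the crosstalk signal by the part of
S that actually co-locates with regulatory structure. With empty GRNs
(mu undefined) scaling is skipped and the off-diagonal signal carries X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .crosstalk import CrosstalkMatrix
from .grn import CellTypeGRN

__all__ = ["JointSimilarity", "scaling_factor", "assemble_joint"]


@dataclass
class JointSimilarity:
    X: np.ndarray
    mu: float
    s: float
    node_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        m = self.X.shape[0]
        if self.X.ndim != 2 or self.X.shape != (m, m) or m % 2:
            raise ValueError("joint matrix must be square with even dimension")
        if len(self.node_names) != m:
            raise ValueError("node_names length must equal matrix dimension")
        if not np.array_equal(self.X, self.X.T):
            raise ValueError("joint matrix must be exactly symmetric")
        if (self.X < 0).any() or not np.isfinite(self.X).all():
            raise ValueError("joint matrix entries must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0] // 2

    def degree(self) -> np.ndarray:
        """Row sums of X — the diagonal of D used by the embedder."""
        return self.X.sum(axis=1)


def scaling_factor(
    w_a: CellTypeGRN,
    w_b: CellTypeGRN,
    S: CrosstalkMatrix,
    mode: Literal["dense", "sparse_aware"] = "sparse_aware",
    support: Literal["union", "intersection"] = "union",
) -> tuple[float, float]:
    """Compute (mu, s) for the chosen mode.

    Returns mu = 0 for the degenerate all-zero-GRN case; ``assemble_joint``
    then skips block scaling.
    """
    n = len(S.gene_order)
    if w_a.W.shape != (n, n) or w_b.W.shape != (n, n):
        raise ValueError("GRNs and crosstalk matrix must share one gene order")
    total_w = float(w_a.W.sum() + w_b.W.sum())
    if mode == "dense":
        s = float(S.S.sum())
    elif mode == "sparse_aware":
        if support == "union":
            mask = (w_a.W != 0) | (w_b.W != 0)
        else:
            mask = (w_a.W != 0) & (w_b.W != 0)
        s = float(S.S[mask].sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if total_w == 0.0:
        warnings.warn("both GRNs are empty; mu=0, diagonal blocks left unscaled")
        return 0.0, s
    if s == 0.0:
        raise ValueError(
            "no crosstalk signal at GRN support (s=0); try mode='dense'"
        )
    return total_w / (2.0 * s), s


def assemble_joint(
    w_a: CellTypeGRN,
    w_b: CellTypeGRN,
    S: CrosstalkMatrix,
    mu: float,
    s: float = float("nan"),
    type_a: str = "A",
    type_b: str = "B",
) -> JointSimilarity:
    """Assemble X = [[W_A', S], [S.T, W_B']] with W' = W/mu (W when mu=0)."""
    n = len(S.gene_order)
    if w_a.W.shape != (n, n) or w_b.W.shape != (n, n):
        raise ValueError("dimension mismatch between GRNs and crosstalk matrix")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    scale = 1.0 / mu if mu > 0 else 1.0
    X = np.block([[w_a.W * scale, S.S], [S.S.T, w_b.W * scale]])
    names = [f"{g}@{type_a}" for g in S.gene_order] + [f"{g}@{type_b}" for g in S.gene_order]
    return JointSimilarity(X, float(mu), float(s), names)
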