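"""Empirical-percentile significance of ligand-receptor pairs.

For each candidate L-R pair the Euclidean distance between the ligand's
latent coordinate in the sender block and the receptor's in the receiver
block is compared against a null distribution: the distances of all
cross-type gene pairs that are NOT in the L-R database. The p-value is the
weak empirical percentile

    p = #{d in null : d <= dist} / #null

so a pair that sits unusually close in latent space gets a small p. Pairs
with p below the threshold (0.05 by default) are called significant. No
multiple-testing correction is applied by default; an optional
Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .crosstalk import CrosstalkMatrix
from .io import InteractionCall, LRDatabase

__all__ = [
    "NullDistribution",
    "cross_distance",
    "build_null",
    "percentile_pvalue",
    "call_interactions",
    "bh_adjust",
]

DEFAULT_THRESHOLD = 0.05
DEFAULT_MAX_NULL_PAIRS = 200_000


@dataclass
class NullDistribution:
    """Sorted latent distances of cross-type non-L-R gene pairs."""

    distances: np.ndarray
    subsampled: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.distances = np.sort(np.asarray(self.distances, dtype=float))
        if self.distances.size == 0:
            raise ValueError("null distribution is empty")
        if (self.distances < 0).any() or not np.isfinite(self.distances).all():
            raise ValueError("null distances must be finite and non-negative")
        if self.distances.size < 100:
            import warnings

            warnings.warn(
                f"null distribution has only {self.distances.size} pairs; "
                "percentile p-values will be coarse"
            )

    @property
    def size(self) -> int:
        return int(self.distances.size)


def cross_distance(Y_A: np.ndarray, Y_B: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance between sender-gene i and receiver-gene j embeddings."""
    Y_A, Y_B = np.asarray(Y_A, float), np.asarray(Y_B, float)
    if not (0 <= i < Y_A.shape[0]) or not (0 <= j < Y_B.shape[0]):
        raise IndexError(f"gene index out of range: i={i}, j={j}")
    return float(np.linalg.norm(Y_A[i] - Y_B[j]))


def build_null(
    Y_A: np.ndarray,
    Y_B: np.ndarray,
    lrdb: LRDatabase,
    gene_order: list[str],
    max_null_pairs: int = DEFAULT_MAX_NULL_PAIRS,
    seed: int = 0,
) -> NullDistribution:
    """Distances of all cross-type gene pairs not present in the L-R database.

    If more than ``max_null_pairs`` pairs remain, a uniform seeded
    subsample keeps the null tractable.
    """
    Y_A, Y_B = np.asarray(Y_A, float), np.asarray(Y_B, float)
    n = len(gene_order)
    if Y_A.shape[0] != n or Y_B.shape[0] != n:
        raise ValueError("embeddings and gene order disagree on n")
    D = cdist(Y_A, Y_B)
    mask = np.ones((n, n), dtype=bool)
    index = {g: k for k, g in enumerate(gene_order)}
    for lig, rec in lrdb.pairs:
        if lig in index and rec in index:
            mask[index[lig], index[rec]] = False
    if not mask.any():
        raise ValueError("every cross-type pair is in the L-R database; null is empty")
    dists = D[mask]
    subsampled = False
    if dists.size > max_null_pairs:
        rng = np.random.default_rng(seed)
        dists = rng.choice(dists, size=max_null_pairs, replace=False)
        subsampled = True
    return NullDistribution(dists, subsampled=subsampled, seed=seed)


def percentile_pvalue(null: NullDistribution, dist_i: float) -> float:
    """Weak empirical percentile of *dist_i* in the null, as a p-value in [0, 1]."""
    if dist_i < 0:
        raise ValueError("distance must be non-negative")
    count = int(np.searchsorted(null.distances, dist_i, side="right"))
    return count / null.size


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_interactions(
    Y_A: np.ndarray,
    Y_B: np.ndarray,
    S: CrosstalkMatrix,
    lrdb: LRDatabase,
    sender: str = "A",
    receiver: str = "B",
    threshold: float = DEFAULT_THRESHOLD,
    max_null_pairs: int = DEFAULT_MAX_NULL_PAIRS,
    seed: int = 0,
    adjust: bool = False,
) -> list[InteractionCall]:
    """Score every database L-R pair present in the data and flag significance.

    The ligand is looked up among sender-block rows (Y_A), the receptor
    among receiver-block rows (Y_B); database pairs whose genes are absent
    from the shared gene order are skipped. Calls come back sorted by
    p-value, ties broken by latent distance.
    """
    gene_order = S.gene_order
    index = {g: k for k, g in enumerate(gene_order)}
    present = [(l, r) for l, r in lrdb.pairs if l in index and r in index]
    if not present:
        sought = sorted({g for p in lrdb.pairs for g in p})
        raise ValueError(
            "no L-R database pair has both genes in the data; sought: "
            + ", ".join(sought[:20])
        )
    null = build_null(Y_A, Y_B, lrdb, gene_order, max_null_pairs=max_null_pairs, seed=seed)
    dists = [cross_distance(Y_A, Y_B, index[l], index[r]) for l, r in present]
    pvals = np.array([percentile_pvalue(null, d) for d in dists])
    if adjust:
        pvals = bh_adjust(pvals)
    calls = [
        InteractionCall(
            ligand=l,
            receptor=r,
            sender=sender,
            receiver=receiver,
            crosstalk_score=float(S.S[index[l], index[r]]),
            latent_distance=float(d),
            p_value=float(p),
            significant=bool(p < threshold),
        )
        for (l, r), d, p in zip(present, dists, pvals)
    ]
    calls.sort(key=lambda c: (c.p_value, c.latent_distance))
    return calls
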