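"""End-to-end interaction caller as a single sklearn-style estimator.

``ScSDNE.fit`` runs the full chain on an annotated expression matrix:

    QC filter -> normalize -> HVG -> per-type means -> crosstalk S
    -> per-type GRNs -> scaling mu -> joint matrix X -> SDNE embedding
    -> null distribution -> percentile p-values -> significant calls

All intermediate objects are exposed as fitted attributes so each stage can
be inspected or re-used.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import preprocess as pp
from .crosstalk import compute_c, crosstalk_matrix
from .grn import CellTypeGRN, coexpression_grn, load_grn
from .io import AnnotatedExpression, LRDatabase
from .joint import assemble_joint, scaling_factor
from .sdne import SDNEEmbedder
from .significance import DEFAULT_MAX_NULL_PAIRS, DEFAULT_THRESHOLD, call_interactions

__all__ = ["ScSDNE"]


class ScSDNE(BaseEstimator):
    """Ligand-receptor interaction caller for one sender/receiver type pair.

    Parameters
    ----------
    sender, receiver : str
        Cell-type labels whose genes occupy the A (sender) and B (receiver)
        blocks of the joint matrix.
    min_genes_per_cell, max_mito_fraction, normalize_scale, n_hvg, mito_prefix
        QC/normalization/HVG settings (see :class:`~scsdne.preprocess.PreprocessConfig`).
    force_include_lr : bool
        Keep L-R database genes in the HVG set regardless of dispersion rank.
    means_on_counts : bool
        Compute per-type means and the crosstalk constant c on raw counts
        instead of normalized values.
    grn_backend : {"coexpression", "precomputed"}
        Source of the per-type GRNs; "precomputed" reads ``grn_a_path`` /
        ``grn_b_path``.
    top_k_edges : int or None
        Edges kept by the co-expression backend; None means 1.5 per gene,
        a budget at which genuine co-regulation dominates noise edges.
    mu_mode : {"sparse_aware", "dense"}
        Scaling-factor variant balancing GRN weight against crosstalk.
    latent_dim, hidden_dims, epochs, learning_rate, alpha_first, nu_reg,
    constraint_mode, penalty_weight, tol
        Embedder settings (see :class:`~scsdne.sdne.SDNEEmbedder`).
    threshold : float
        Raw p-value cutoff for the significance flag (0.05 by default).
    adjust : bool
        Apply Benjamini-Hochberg adjustment before thresholding.
    random_state : int
        Seed for embedder initialization and null subsampling.

    Attributes
    ----------
    interactions_ : list of InteractionCall
        One scored call per database pair present in the data, sorted by
        p-value then latent distance.
    interactions_frame_ : DataFrame
        The same calls as a tidy table.
    embedding_, gene_order_, S_, mu_, s_, c_, constraint_residual_ : see stages.
    """

    def __init__(
        self,
        sender: str = "A",
        receiver: str = "B",
        min_genes_per_cell: int = 200,
        max_mito_fraction: float = 0.2,
        normalize_scale: float = 1e4,
        n_hvg: int = 2000,
        mito_prefix: str = "MT-",
        force_include_lr: bool = True,
        means_on_counts: bool = False,
        grn_backend: Literal["coexpression", "precomputed"] = "coexpression",
        grn_a_path: str | None = None,
        grn_b_path: str | None = None,
        top_k_edges: int | None = None,
        mu_mode: Literal["sparse_aware", "dense"] = "sparse_aware",
        mu_support: Literal["union", "intersection"] = "union",
        latent_dim: int | None = None,
        hidden_dims: tuple[int, ...] | None = None,
        epochs: int = 200,
        learning_rate: float = 0.01,
        alpha_first: float = 1.0,
        nu_reg: float = 1.0,
        constraint_mode: Literal["stiefel", "penalty"] = "stiefel",
        penalty_weight: float = 1000.0,
        tol: float = 1e-3,
        threshold: float = DEFAULT_THRESHOLD,
        max_null_pairs: int = DEFAULT_MAX_NULL_PAIRS,
        adjust: bool = False,
        random_state: int = 0,
    ):
        self.sender = sender
        self.receiver = receiver
        self.min_genes_per_cell = min_genes_per_cell
        self.max_mito_fraction = max_mito_fraction
        self.normalize_scale = normalize_scale
        self.n_hvg = n_hvg
        self.mito_prefix = mito_prefix
        self.force_include_lr = force_include_lr
        self.means_on_counts = means_on_counts
        self.grn_backend = grn_backend
        self.grn_a_path = grn_a_path
        self.grn_b_path = grn_b_path
        self.top_k_edges = top_k_edges
        self.mu_mode = mu_mode
        self.mu_support = mu_support
        self.latent_dim = latent_dim
        self.hidden_dims = hidden_dims
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.alpha_first = alpha_first
        self.nu_reg = nu_reg
        self.constraint_mode = constraint_mode
        self.penalty_weight = penalty_weight
        self.tol = tol
        self.threshold = threshold
        self.max_null_pairs = max_null_pairs
        self.adjust = adjust
        self.random_state = random_state

    def fit(self, expr: AnnotatedExpression, lrdb: LRDatabase) -> "ScSDNE":
        if self.sender == self.receiver:
            raise ValueError("sender and receiver types must differ")
        cfg = pp.PreprocessConfig(
            min_genes_per_cell=self.min_genes_per_cell,
            max_mito_fraction=self.max_mito_fraction,
            normalize_scale=self.normalize_scale,
            n_hvg=self.n_hvg,
            mito_prefix=self.mito_prefix,
        )
        # restrict to the two types of interest before any statistics
        cols = np.concatenate(
            [expr.cells_of_type(self.sender), expr.cells_of_type(self.receiver)]
        )
        expr = expr.subset_cells(np.sort(cols))
        filtered = pp.filter_cells(expr, cfg)
        normed = pp.normalize(filtered, cfg)
        lr_genes = sorted({g for pair in lrdb.pairs for g in pair})
        hvg = pp.select_hvg(
            normed, cfg, force_include=lr_genes if self.force_include_lr else None
        )
        self.gene_order_ = hvg
        working = (filtered if self.means_on_counts else normed).subset_genes(hvg)

        u_a, u_b = pp.mean_by_type(working, self.sender, self.receiver)
        c = compute_c(working, self.sender, self.receiver)
        S = crosstalk_matrix(u_a, u_b, c, gene_order=hvg)
        self.u_a_, self.u_b_, self.c_, self.S_ = u_a, u_b, c, S

        if self.grn_backend == "precomputed":
            if not self.grn_a_path or not self.grn_b_path:
                raise ValueError("precomputed backend requires grn_a_path and grn_b_path")
            grn_a = load_grn(self.grn_a_path, hvg)
            grn_b = load_grn(self.grn_b_path, hvg)
            grn_a = CellTypeGRN(grn_a.W, cell_type=self.sender, backend_tag="precomputed")
            grn_b = CellTypeGRN(grn_b.W, cell_type=self.receiver, backend_tag="precomputed")
        elif self.grn_backend == "coexpression":
            normed_sub = normed.subset_genes(hvg)
            k = self.top_k_edges if self.top_k_edges is not None else int(1.5 * len(hvg))
            grn_a = coexpression_grn(normed_sub, self.sender, k)
            grn_b = coexpression_grn(normed_sub, self.receiver, k)
        else:
            raise ValueError(f"unknown grn_backend {self.grn_backend!r}")
        self.grn_a_, self.grn_b_ = grn_a, grn_b

        mu, s = scaling_factor(grn_a, grn_b, S, mode=self.mu_mode, support=self.mu_support)
        joint = assemble_joint(
            grn_a, grn_b, S, mu, s, type_a=self.sender, type_b=self.receiver
        )
        self.mu_, self.s_, self.joint_ = mu, s, joint

        embedder = SDNEEmbedder(
            latent_dim=self.latent_dim,
            hidden_dims=self.hidden_dims,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            alpha_first=self.alpha_first,
            nu_reg=self.nu_reg,
            constraint_mode=self.constraint_mode,
            penalty_weight=self.penalty_weight,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(joint)
        self.embedder_ = embedder
        self.embedding_ = embedder.embedding_
        self.constraint_residual_ = embedder.constraint_residual_
        self.training_log_ = embedder.training_log_

        n = len(hvg)
        self.interactions_ = call_interactions(
            self.embedding_[:n],
            self.embedding_[n:],
            S,
            lrdb,
            sender=self.sender,
            receiver=self.receiver,
            threshold=self.threshold,
            max_null_pairs=self.max_null_pairs,
            seed=self.random_state,
            adjust=self.adjust,
        )
        self.interactions_frame_ = pd.DataFrame(
            {
                "ligand": [c_.ligand for c_ in self.interactions_],
                "receptor": [c_.receptor for c_ in self.interactions_],
                "sender_type": [c_.sender for c_ in self.interactions_],
                "receiver_type": [c_.receiver for c_ in self.interactions_],
                "crosstalk_score": [c_.crosstalk_score for c_ in self.interactions_],
                "latent_distance": [c_.latent_distance for c_ in self.interactions_],
                "p_value": [c_.p_value for c_ in self.interactions_],
                "significant": [c_.significant for c_ in self.interactions_],
            }
        )
        return self

    def significant_(self) -> pd.DataFrame:
        """Convenience view: only the calls below the threshold."""
        if not hasattr(self, "interactions_frame_"):
            raise RuntimeError("call fit first")
        return self.interactions_frame_[self.interactions_frame_["significant"]]
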