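"""Structural deep network embedding of the joint gene graph.

Each node of the joint similarity matrix X gets a d-dimensional latent
coordinate y_i. A stacked sigmoid decoder reconstructs the node's
adjacency row from y_i, so nodes with similar neighbourhoods receive
similar codes (second-order proximity), while a graph Laplacian term pulls
directly connected nodes together (first-order proximity). The mixed
objective is

    L_mix = ||X_hat - X||_F^2  +  2 tr(Y.T L Y)  +  (nu/2) sum_k ||W_k||_F^2

with L = D - X and D the diagonal degree matrix (D_ii = sum_j X_ij). To
prevent the trivial collapse Y = 0 the embedding is constrained to the
generalized Stiefel manifold Y.T D Y = I_d.

The code matrix Y is optimized directly (the encoder half of the classic
architecture is subsumed by free optimization of the codes). This is what
makes the constraint attainable at any d, including the full dimension
d = 2n: a row-wise encoder caps the numerical rank of Y near rank(X), and
the crosstalk block of X is close to low rank, so D-orthogonality through
an encoder output is unsatisfiable beyond that rank. Two constraint modes:

* ``stiefel`` (default): each step projects the gradient onto the
  manifold's tangent space {xi : xi.T D Y + Y.T D xi = 0}, takes an Adam
  step, and retracts via the polar map Y -> Y (Y.T D Y)^{-1/2}; the
  constraint residual stays at machine precision.
* ``penalty``: a quadratic penalty  w * ||Y.T D Y - I_d||_F^2  is added to
  the objective and ordinary unconstrained Adam steps are taken; the
  residual settles near the penalized optimum's O(1/w) level.

Notably, at full dimension the exact constraint forces Y = D^{-1/2} Q with
Q orthogonal, so all cross-node distances reduce to the closed form
dist^2(i, j) = 1/D_ii + 1/D_jj regardless of where training stops: the
full-dimensional model ranks node pairs by joint connectivity.

Training is full-batch Adam in double precision; with a fixed seed the
trajectory is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.base import BaseEstimator

from .joint import JointSimilarity

__all__ = [
    "SDNEConfig",
    "Embedding",
    "SDNEEmbedder",
    "loss_second_order",
    "loss_first_order",
    "loss_regularizer",
    "fit_embedding",
]

_D_EPS = 1e-8  # floor on degree diagonal: keeps Y.T D Y invertible for isolated nodes


def loss_second_order(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Reconstruction loss: squared Frobenius norm of (X_hat - X)."""
    X, X_hat = np.asarray(X, float), np.asarray(X_hat, float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    return float(((X_hat - X) ** 2).sum())


def loss_first_order(X: np.ndarray, Y: np.ndarray) -> float:
    """Laplacian loss 2 tr(Y.T L Y) = sum_ij X_ij ||y_i - y_j||^2."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("X must be square")
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"Y has {Y.shape[0]} rows but X is {X.shape[0]}x{X.shape[1]}")
    L = np.diag(X.sum(axis=1)) - X
    return float(2.0 * np.trace(Y.T @ L @ Y))


def loss_regularizer(
    encoder_weights: list[np.ndarray],
    decoder_weights: list[np.ndarray],
    nu_reg: float = 1.0,
) -> float:
    """Weight decay: nu/2 * sum of squared Frobenius norms of all weight matrices."""
    if not encoder_weights and not decoder_weights:
        raise ValueError("weight lists are empty")
    total = sum(float((W**2).sum()) for W in encoder_weights)
    total += sum(float((W**2).sum()) for W in decoder_weights)
    return nu_reg * 0.5 * total


@dataclass
class SDNEConfig:
    """Training configuration for the joint-graph embedder."""

    latent_dim: int = 16
    hidden_dims: tuple[int, ...] = (128,)
    epochs: int = 200
    learning_rate: float = 0.01
    alpha_first: float = 1.0
    nu_reg: float = 1.0
    seed: int = 0
    constraint_mode: Literal["stiefel", "penalty"] = "stiefel"
    penalty_weight: float = 1000.0
    tol: float = 1e-3


@dataclass
class Embedding:
    """Latent coordinates for all 2n joint-graph nodes."""

    Y: np.ndarray
    node_names: list[str]
    constraint_residual: float

    @property
    def Y_A(self) -> np.ndarray:
        return self.Y[: self.Y.shape[0] // 2]

    @property
    def Y_B(self) -> np.ndarray:
        return self.Y[self.Y.shape[0] // 2 :]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _inv_sqrt_psd(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    vals, vecs = np.linalg.eigh(C)
    vals = np.maximum(vals, 1e-30)
    return (vecs * (vals**-0.5)) @ vecs.T


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class SDNEEmbedder(BaseEstimator):
    """Graph embedder with a reconstruction decoder and D-orthogonality constraint.

    Parameters mirror :class:`SDNEConfig`; ``random_state`` is the training
    seed. Fit on a :class:`~scsdne.joint.JointSimilarity` (or a raw
    symmetric non-negative ndarray). ``latent_dim=None`` requests the
    full-dimensional embedding d = 2n; ``hidden_dims`` sets the decoder's
    hidden widths (None picks (128,) for low-d and a direct single sigmoid
    layer for full d).

    Attributes
    ----------
    embedding_ : ndarray of shape (2n, latent_dim)
        Latent coordinates, one row per joint-graph node.
    constraint_residual_ : float
        Final ||Y.T D Y - I_d||_F.
    training_log_ : list of dict
        Per-epoch loss components and constraint residual.
    """

    def __init__(
        self,
        latent_dim: int | None = 16,
        hidden_dims: tuple[int, ...] | None = (128,),
        epochs: int = 200,
        learning_rate: float = 0.01,
        alpha_first: float = 1.0,
        nu_reg: float = 1.0,
        constraint_mode: Literal["stiefel", "penalty"] = "stiefel",
        penalty_weight: float = 1000.0,
        tol: float = 1e-3,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_dims = hidden_dims
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.alpha_first = alpha_first
        self.nu_reg = nu_reg
        self.constraint_mode = constraint_mode
        self.penalty_weight = penalty_weight
        self.tol = tol
        self.random_state = random_state

    # -- internal plumbing ---------------------------------------------------

    def _resolved_dims(self, m: int) -> tuple[int, tuple[int, ...]]:
        """Resolve latent/hidden sizes; None latent means full dimension d = 2n."""
        d = m if self.latent_dim is None else self.latent_dim
        if self.hidden_dims is None:
            hidden: tuple[int, ...] = () if d >= m else (128,)
        else:
            hidden = tuple(self.hidden_dims)
        return d, hidden

    def _init_params(self, m: int, d: int, hidden: tuple[int, ...], rng: np.random.Generator):
        """Decoder weights: widths [d, *reversed(hidden), m], Glorot-uniform init."""
        dec_dims = [d, *reversed(hidden), m]

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        return [(glorot(a, b), np.zeros(b)) for a, b in zip(dec_dims, dec_dims[1:])]

    @staticmethod
    def _decode(Y, dec):
        acts = [Y]
        H = Y
        for W, b in dec:
            H = _sigmoid(H @ W + b)
            acts.append(H)
        return H, acts

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y=None) -> "SDNEEmbedder":
        if isinstance(X, JointSimilarity):
            node_names = list(X.node_names)
            A = X.X
        else:
            A = np.asarray(X, dtype=float)
            node_names = [f"node{i}" for i in range(A.shape[0])]
        m = A.shape[0]
        d, hidden = self._resolved_dims(m)
        if d < 2:
            raise ValueError("latent_dim must be >= 2")
        if d > m:
            raise ValueError(f"latent_dim={d} exceeds node count {m}")
        deg = np.maximum(A.sum(axis=1), _D_EPS)
        Lap = np.diag(deg) - A  # D floor only affects isolated nodes' self-term

        rng = np.random.default_rng(self.random_state)
        dec = self._init_params(m, d, hidden, rng)
        stiefel = self.constraint_mode == "stiefel"
        if self.constraint_mode not in ("stiefel", "penalty"):
            raise ValueError(f"unknown constraint_mode {self.constraint_mode!r}")

        # free code matrix, initialized on (or near) the constraint manifold
        Y = rng.standard_normal((m, d))
        Y = Y @ _inv_sqrt_psd((Y * deg[:, None]).T @ Y)
        params = [Y] + [p for Wb in dec for p in Wb]
        opt = _Adam([p.shape for p in params], self.learning_rate)

        log: list[dict] = []
        for epoch in range(self.epochs):
            Y = params[0]
            X_hat, dec_acts = self._decode(Y, dec)

            resid = X_hat - A
            l2nd = float((resid**2).sum())
            l1st = self.alpha_first * float(2.0 * np.trace(Y.T @ (Lap @ Y)))
            lreg = loss_regularizer([], [W for W, _ in dec], self.nu_reg)
            C = (Y * deg[:, None]).T @ Y - np.eye(d)
            residual = float(np.linalg.norm(C))
            pen = self.penalty_weight * float((C**2).sum()) if not stiefel else 0.0
            total = l2nd + l1st + lreg + pen
            if not np.isfinite(total):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            log.append(
                {
                    "epoch": epoch,
                    "loss_total": total,
                    "loss_first": l1st,
                    "loss_second": l2nd,
                    "loss_reg": lreg,
                    "penalty": pen,
                    "constraint_residual": residual,
                }
            )

            # gradient wrt Y: Laplacian term (+ penalty term in penalty mode)
            dY = self.alpha_first * 4.0 * (Lap @ Y)
            if not stiefel:
                dY = dY + self.penalty_weight * 4.0 * (deg[:, None] * Y) @ C
            # decoder backprop from reconstruction loss
            grads_dec = []
            delta = 2.0 * resid * (dec_acts[-1] * (1.0 - dec_acts[-1]))
            for k in range(len(dec) - 1, -1, -1):
                W, _ = dec[k]
                H_in = dec_acts[k]
                gW = H_in.T @ delta + self.nu_reg * W
                gb = delta.sum(axis=0)
                grads_dec.append((gW, gb))
                delta = delta @ W.T
                if k > 0:
                    delta = delta * (H_in * (1.0 - H_in))
            grads_dec.reverse()
            dY = dY + delta  # reconstruction gradient reaching the bottleneck

            if stiefel:
                # Riemannian gradient: D-metric, projected onto the tangent
                # space {xi : xi.T D Y + Y.T D xi = 0}
                G = dY / deg[:, None]
                sym = 0.5 * (Y.T @ dY + dY.T @ Y)
                dY = G - Y @ sym
            flat_grads = [dY] + [g for Wb in grads_dec for g in Wb]
            opt.step(params, flat_grads)
            if stiefel:
                # polar retraction back onto the manifold (well conditioned:
                # the iterate is a small step away from D-orthonormality)
                Ynew = params[0]
                Ynew[:] = Ynew @ _inv_sqrt_psd((Ynew * deg[:, None]).T @ Ynew)

        Y = params[0]
        C = (Y * deg[:, None]).T @ Y - np.eye(d)
        self.embedding_ = Y
        self.constraint_residual_ = float(np.linalg.norm(C))
        self.training_log_ = log
        self.node_names_ = node_names
        self.degree_ = deg
        self._decoder = dec
        if stiefel and self.constraint_residual_ > self.tol:
            raise FloatingPointError(
                f"constraint residual {self.constraint_residual_:.3g} exceeds tol {self.tol}"
            )
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def fit_embedding(joint: JointSimilarity, cfg: SDNEConfig) -> tuple[Embedding, list[dict]]:
    """Functional wrapper: train an embedder on a joint matrix, return (embedding, log)."""
    est = SDNEEmbedder(
        latent_dim=cfg.latent_dim,
        hidden_dims=cfg.hidden_dims,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        alpha_first=cfg.alpha_first,
        nu_reg=cfg.nu_reg,
        constraint_mode=cfg.constraint_mode,
        penalty_weight=cfg.penalty_weight,
        tol=cfg.tol,
        random_state=cfg.seed,
    ).fit(joint)
    emb = Embedding(est.embedding_, est.node_names_, est.constraint_residual_)
    return emb, est.training_log_
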