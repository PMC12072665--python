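"""Self-contained two-cell-type fixtures with planted ligand-receptor signal.

The generator draws negative-binomial counts for two annotated cell types
and plants two kinds of structure, matching the two information channels
the joint similarity matrix combines:

* planted L-R pairs: the ligand gene is highly expressed in the sender
  type and the receptor gene in the receiver type, so their crosstalk
  score (product of per-type means) is large — the lever the caller
  actually uses. Decoy L-R pairs sit in the database but express at
  baseline in both types.
* co-regulation modules: genes outside the L-R database share a per-cell
  latent factor within each cell type (Gaussian copula over the NB
  marginals), giving within-module rank correlation near ``module_corr``
  that the co-expression GRN backend can recover.

Counts are integers; per-type per-gene empirical means converge to the
specified means as cells grow. Everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import csr_matrix
from scipy.stats import nbinom, norm
from sklearn.metrics import roc_auc_score

from .io import AnnotatedExpression, InteractionCall, LRDatabase

__all__ = ["SyntheticSpec", "generate", "evaluate_recovery", "write_fixture"]


@dataclass
class SyntheticSpec:
    """Generator conditions for the planted-signal fixture.

    Defaults describe a modest two-type tissue: 300 genes, 300 cells per
    type, 20 true L-R pairs whose partners express five-fold over baseline,
    80 decoy pairs, and 10 co-regulation modules among the non-L-R genes
    with latent-factor correlation 0.5. The NB dispersion (size) of 1.0
    gives the strong overdispersion typical of droplet scRNA-seq counts.
    """

    n_genes: int = 300
    n_cells_per_type: int = 300
    n_planted_lr: int = 20
    n_decoy_lr: int = 80
    lr_mean_high: float = 5.0
    base_mean: float = 1.0
    nb_dispersion: float = 1.0
    n_grn_modules: int = 10
    module_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        n_pairs = self.n_planted_lr + self.n_decoy_lr
        if n_pairs > self.n_genes:
            raise ValueError("n_planted_lr + n_decoy_lr exceeds n_genes")
        pool = self.pool_size
        if self.n_planted_lr > pool:
            raise ValueError(
                f"n_planted_lr={self.n_planted_lr} exceeds the ligand pool size {pool}"
            )
        if self.n_decoy_lr > (pool - self.n_planted_lr) * pool:
            raise ValueError("n_decoy_lr exceeds the decoy pair capacity of the gene pools")
        if self.lr_mean_high <= self.base_mean:
            raise ValueError("lr_mean_high must exceed base_mean")
        if not 0.0 < self.module_corr < 1.0:
            raise ValueError("module_corr must be in (0, 1)")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")

    @property
    def pool_size(self) -> int:
        """Size of each of the disjoint ligand and receptor gene pools.

        Pairs use distinct genes while the gene budget allows (as in real
        L-R databases, where gene sharing across pairs is the exception);
        past ``n_genes // 2`` pairs, genes are reused across pairs.
        """
        return min(self.n_planted_lr + self.n_decoy_lr, self.n_genes // 2)


def _nb_params(mean: float, size: float) -> tuple[float, float]:
    # NB with mean m and size (shape) r: p = r / (r + m), var = m + m^2/r
    return size, size / (size + mean)


def _copula_counts(
    rng: np.random.Generator,
    n_genes: int,
    n_cells: int,
    mean: float,
    size: float,
    rho: float,
) -> np.ndarray:
    """NB counts with shared-factor Gaussian copula across genes."""
    factor = rng.standard_normal(n_cells)
    noise = rng.standard_normal((n_genes, n_cells))
    z = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * noise
    u = np.clip(norm.cdf(z), 1e-12, 1.0 - 1e-12)
    r, p = _nb_params(mean, size)
    return nbinom.ppf(u, r, p).astype(float)


def generate(spec: SyntheticSpec) -> tuple[AnnotatedExpression, LRDatabase, pd.DataFrame]:
    """Draw one fixture: counts + annotations, L-R database, truth table.

    The truth table has columns ``ligand``, ``receptor``, ``planted``
    (bool), one row per database pair.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_planted_lr + spec.n_decoy_lr
    a = spec.pool_size
    lig_pool = [f"LG{k:04d}" for k in range(a)]
    rec_pool = [f"RC{k:04d}" for k in range(a)]
    others = [f"G{k:04d}" for k in range(spec.n_genes - 2 * a)]
    genes = lig_pool + rec_pool + others
    # pair k -> pool slots; the shifted second index is a Latin-square walk,
    # so pairs stay unique even when k wraps past the pool size
    pair_slots = [(k % a, (k % a + k // a) % a) for k in range(n_pairs)]
    ligands = [lig_pool[i] for i, _ in pair_slots]
    receptors = [rec_pool[j] for _, j in pair_slots]
    n_cells = spec.n_cells_per_type
    cells = [f"cellA{i:04d}" for i in range(n_cells)] + [
        f"cellB{i:04d}" for i in range(n_cells)
    ]
    cell_types = {c: ("A" if c.startswith("cellA") else "B") for c in cells}

    # per-gene per-type means: planted ligands high in A, receptors high in B
    mean_a = np.full(spec.n_genes, spec.base_mean)
    mean_b = np.full(spec.n_genes, spec.base_mean)
    mean_a[: spec.n_planted_lr] = spec.lr_mean_high  # planted ligand slots
    mean_b[a : a + spec.n_planted_lr] = spec.lr_mean_high  # planted receptor slots

    mat = np.zeros((spec.n_genes, 2 * n_cells))
    # L-R genes: independent NB draws at their type-specific means
    for means, sl in (
        (mean_a, slice(0, n_cells)),
        (mean_b, slice(n_cells, 2 * n_cells)),
    ):
        for g in range(2 * a):
            r, p = _nb_params(means[g], spec.nb_dispersion)
            mat[g, sl] = rng.negative_binomial(r, p, size=n_cells)

    # module genes: shared latent factor within each module and cell type
    module_genes = np.arange(2 * a, spec.n_genes)
    if module_genes.size and spec.n_grn_modules > 0:
        splits = np.array_split(module_genes, spec.n_grn_modules)
        for sl in (slice(0, n_cells), slice(n_cells, 2 * n_cells)):
            for members in splits:
                if members.size == 0:
                    continue
                mat[members, sl] = _copula_counts(
                    rng,
                    members.size,
                    n_cells,
                    spec.base_mean,
                    spec.nb_dispersion,
                    spec.module_corr,
                )

    expr = AnnotatedExpression(mat, genes, cells, cell_types)
    pairs = tuple(zip(ligands, receptors))
    lrdb = LRDatabase(pairs)
    truth = pd.DataFrame(
        {
            "ligand": ligands,
            "receptor": receptors,
            "planted": [k < spec.n_planted_lr for k in range(n_pairs)],
        }
    )
    return expr, lrdb, truth


def evaluate_recovery(
    calls: list[InteractionCall],
    truth: pd.DataFrame,
    threshold: float = 0.05,
) -> dict[str, float]:
    """Sensitivity/specificity at *threshold* and ranking AUROC over database pairs.

    AUROC ranks pairs by negative latent distance with planted pairs as
    positives; every truth pair must appear among the calls.
    """
    by_pair = {(c.ligand, c.receptor): c for c in calls}
    missing = [
        (l, r)
        for l, r in zip(truth["ligand"], truth["receptor"])
        if (l, r) not in by_pair
    ]
    if missing:
        raise ValueError(f"truth pairs absent from calls: {missing[:5]}")
    planted = truth["planted"].to_numpy(bool)
    p = np.array(
        [by_pair[(l, r)].p_value for l, r in zip(truth["ligand"], truth["receptor"])]
    )
    d = np.array(
        [
            by_pair[(l, r)].latent_distance
            for l, r in zip(truth["ligand"], truth["receptor"])
        ]
    )
    n_planted = int(planted.sum())
    n_decoy = int((~planted).sum())
    sens = float((p[planted] < threshold).mean()) if n_planted else float("nan")
    spec = float((p[~planted] >= threshold).mean()) if n_decoy else float("nan")
    auroc = (
        float(roc_auc_score(planted, -d)) if 0 < n_planted < planted.size else float("nan")
    )
    return {"sensitivity": sens, "specificity": spec, "auroc": auroc}


def write_fixture(
    expr: AnnotatedExpression,
    lrdb: LRDatabase,
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Dump a fixture in the same MTX/TSV dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.txt",
        "cells": out / "cells.txt",
        "celltypes": out / "celltypes.tsv",
        "lrdb": out / "lrdb.tsv",
    }
    mmwrite(paths["matrix"], csr_matrix(expr.matrix))
    paths["genes"].write_text("\n".join(expr.gene_names) + "\n")
    paths["cells"].write_text("\n".join(expr.cell_names) + "\n")
    with open(paths["celltypes"], "w") as fh:
        for c in expr.cell_names:
            fh.write(f"{c}\t{expr.cell_types[c]}\n")
    with open(paths["lrdb"], "w") as fh:
        fh.write("ligand\treceptor\n")
        for lig, rec in lrdb.pairs:
            fh.write(f"{lig}\t{rec}\n")
    if truth is not None:
        paths["truth"] = out / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
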