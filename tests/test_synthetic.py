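import numpy as np
import pytest

from scsdne import InteractionCall, SyntheticSpec, evaluate_recovery, generate
from scsdne.grn import _spearman_abs


class TestGenerate:
    def test_counts_are_nonnegative_integers(self):
        expr, _, _ = generate(SyntheticSpec(n_genes=40, n_cells_per_type=30, n_planted_lr=3, n_decoy_lr=5, seed=0))
        assert (expr.matrix >= 0).all()
        np.testing.assert_array_equal(expr.matrix, np.round(expr.matrix))

    def test_same_seed_identical(self):
        spec = SyntheticSpec(n_genes=30, n_cells_per_type=20, n_planted_lr=2, n_decoy_lr=3, seed=5)
        e1, db1, t1 = generate(spec)
        e2, db2, t2 = generate(spec)
        np.testing.assert_array_equal(e1.matrix, e2.matrix)
        assert db1.pairs == db2.pairs
        assert t1.equals(t2)

    def test_no_planted_means_all_decoy_truth(self):
        _, db, truth = generate(SyntheticSpec(n_genes=30, n_cells_per_type=10, n_planted_lr=0, n_decoy_lr=6, seed=1))
        assert not truth["planted"].any()
        assert len(db) == 6

    def test_planted_ligand_mean_exceeds_decoy_over_seeds(self):
        # Monte-Carlo: at 200 cells/type the planted ligand's empirical mean
        # in the sender type should essentially always beat a decoy ligand's
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            spec = SyntheticSpec(
                n_genes=20, n_cells_per_type=200, n_planted_lr=2, n_decoy_lr=2, seed=seed
            )
            expr, db, truth = generate(spec)
            a_cols = expr.cells_of_type("A")
            idx = {g: i for i, g in enumerate(expr.gene_names)}
            planted_lig = truth.loc[truth.planted, "ligand"].iloc[0]
            decoy_lig = truth.loc[~truth.planted, "ligand"].iloc[0]
            wins += (
                expr.matrix[idx[planted_lig]][a_cols].mean()
                > expr.matrix[idx[decoy_lig]][a_cols].mean()
            )
        assert wins >= 0.95 * n_seeds

    def test_empirical_means_converge(self):
        spec = SyntheticSpec(
            n_genes=30, n_cells_per_type=1000, n_planted_lr=3, n_decoy_lr=3, seed=2
        )
        expr, _, truth = generate(spec)
        idx = {g: i for i, g in enumerate(expr.gene_names)}
        a_cols = expr.cells_of_type("A")
        b_cols = expr.cells_of_type("B")
        for lig in truth.loc[truth.planted, "ligand"]:
            assert expr.matrix[idx[lig]][a_cols].mean() == pytest.approx(
                spec.lr_mean_high, rel=0.1
            )
        for rec in truth.loc[truth.planted, "receptor"]:
            assert expr.matrix[idx[rec]][b_cols].mean() == pytest.approx(
                spec.lr_mean_high, rel=0.1
            )
        for lig in truth.loc[~truth.planted, "ligand"]:
            assert expr.matrix[idx[lig]][a_cols].mean() == pytest.approx(
                spec.base_mean, rel=0.1
            )

    def test_gene_reuse_when_pairs_exceed_half_the_genes(self):
        spec = SyntheticSpec(n_genes=30, n_cells_per_type=10, n_planted_lr=0, n_decoy_lr=20, seed=0)
        _, db, truth = generate(spec)
        assert len(db) == 20  # unique pairs despite gene reuse
        assert len(set(db.pairs)) == 20

    def test_infeasible_specs_error(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_genes=10, n_planted_lr=8, n_decoy_lr=8)
        with pytest.raises(ValueError):
            SyntheticSpec(lr_mean_high=1.0, base_mean=1.0)

    def test_module_correlation_structure(self):
        # within-module rank correlation should clearly exceed between-module
        spec = SyntheticSpec(
            n_genes=60,
            n_cells_per_type=300,
            n_planted_lr=5,
            n_decoy_lr=5,
            n_grn_modules=4,
            module_corr=0.5,
            seed=3,
        )
        expr, _, _ = generate(spec)
        a_cols = expr.cells_of_type("A")
        module_rows = np.arange(20, 60)  # genes beyond the two L-R pools
        rho = _spearman_abs(expr.matrix[np.ix_(module_rows, a_cols)])
        splits = np.array_split(np.arange(40), 4)
        within, between = [], []
        for gi in range(40):
            for gj in range(gi + 1, 40):
                same = any(gi in s and gj in s for s in splits)
                (within if same else between).append(rho[gi, gj])
        assert np.mean(within) > np.mean(between) + 0.1


def test_coexpression_backend_recovers_modules_at_default_spec():
    """Top-k co-expression edges should fall overwhelmingly within modules."""
    from scsdne import coexpression_grn
    from scsdne.preprocess import PreprocessConfig, filter_cells, normalize

    spec = SyntheticSpec(seed=0)
    expr, _, _ = generate(spec)
    cfg = PreprocessConfig(min_genes_per_cell=1, max_mito_fraction=1.0)
    normed = normalize(filter_cells(expr, cfg), cfg)
    a = spec.pool_size
    splits = np.array_split(np.arange(2 * a, spec.n_genes), spec.n_grn_modules)
    gene2mod = {expr.gene_names[g]: mi for mi, s in enumerate(splits) for g in s}
    grn = coexpression_grn(normed, "A", int(1.5 * spec.n_genes))
    iu = np.triu_indices_from(grn.W, 1)
    edges = [(i, j) for i, j, w in zip(*iu, grn.W[iu]) if w > 0]
    within = sum(
        1
        for i, j in edges
        if gene2mod.get(expr.gene_names[i], -1) == gene2mod.get(expr.gene_names[j], -2)
    )
    assert within / len(edges) >= 0.8


class TestEvaluateRecovery:
    def _truth(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "ligand": ["L1", "L2", "L3", "L4"],
                "receptor": ["R1", "R2", "R3", "R4"],
                "planted": [True, True, False, False],
            }
        )

    def _calls(self, dists, ps):
        return [
            InteractionCall(f"L{i+1}", f"R{i+1}", "A", "B", 0.5, d, p, p < 0.05)
            for i, (d, p) in enumerate(zip(dists, ps))
        ]

    def test_perfect_separation_auroc_one(self):
        calls = self._calls([0.1, 0.2, 0.9, 0.8], [0.01, 0.01, 0.5, 0.6])
        m = evaluate_recovery(calls, self._truth())
        assert m["auroc"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_all_insignificant_sens_zero_spec_one(self):
        calls = self._calls([0.5, 0.5, 0.5, 0.5], [1.0, 1.0, 1.0, 1.0])
        m = evaluate_recovery(calls, self._truth())
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0

    def test_random_distances_auroc_near_half(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        n = 100
        truth = pd.DataFrame(
            {
                "ligand": [f"L{i}" for i in range(n)],
                "receptor": [f"R{i}" for i in range(n)],
                "planted": [i < n // 2 for i in range(n)],
            }
        )
        aurocs = []
        for _ in range(20):
            dists = rng.uniform(size=n)
            calls = [
                InteractionCall(f"L{i}", f"R{i}", "A", "B", 0.5, dists[i], 0.5, False)
                for i in range(n)
            ]
            aurocs.append(evaluate_recovery(calls, truth)["auroc"])
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_missing_pair_errors(self):
        calls = self._calls([0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="absent"):
            evaluate_recovery(calls, self._truth())
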