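import numpy as np
import pytest

from scsdne import (
    AnnotatedExpression,
    PreprocessConfig,
    filter_cells,
    mean_by_type,
    normalize,
    select_hvg,
)


def _expr(mat, genes=None, types=None):
    mat = np.asarray(mat, float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    cells = [f"c{i}" for i in range(mat.shape[1])]
    types = types or {c: "A" for c in cells}
    return AnnotatedExpression(mat, genes, cells, types)


class TestFilterCells:
    def test_removes_cell_with_no_detected_genes(self):
        expr = _expr([[1, 0], [2, 0]])
        cfg = PreprocessConfig(min_genes_per_cell=1, max_mito_fraction=1.0)
        out = filter_cells(expr, cfg)
        assert out.cell_names == ["c0"]
        assert out.gene_names == expr.gene_names

    def test_no_op_bounds_are_identity(self, toy_expression):
        cfg = PreprocessConfig(min_genes_per_cell=0, max_mito_fraction=1.0)
        out = filter_cells(toy_expression, cfg)
        np.testing.assert_array_equal(out.matrix, toy_expression.matrix)
        assert out.cell_names == toy_expression.cell_names

    def test_high_mito_cell_removed(self):
        # 4-gene toy: one mito gene; cell c4 is 90% mitochondrial
        mat = np.array(
            [
                [5, 5, 5, 5, 1],
                [3, 2, 4, 1, 0],
                [2, 2, 2, 2, 0],
                [1, 1, 1, 1, 9],  # MT- gene
            ],
            dtype=float,
        )
        expr = _expr(mat, genes=["g1", "g2", "g3", "MT-ND1"])
        cfg = PreprocessConfig(min_genes_per_cell=1, max_mito_fraction=0.2)
        out = filter_cells(expr, cfg)
        assert out.n_cells == 4
        assert "c4" not in out.cell_names

    def test_all_removed_raises_with_advice(self):
        expr = _expr([[0, 0]])
        cfg = PreprocessConfig(min_genes_per_cell=1, max_mito_fraction=1.0)
        with pytest.raises(ValueError, match="relax"):
            filter_cells(expr, cfg)

    @pytest.mark.parametrize("loose,strict", [((1, 1.0), (3, 0.5)), ((0, 0.9), (2, 0.1))])
    def test_loosening_thresholds_is_monotone(self, two_type_counts, loose, strict):
        cfg_loose = PreprocessConfig(min_genes_per_cell=loose[0], max_mito_fraction=loose[1])
        cfg_strict = PreprocessConfig(min_genes_per_cell=strict[0], max_mito_fraction=strict[1])
        kept_loose = set(filter_cells(two_type_counts, cfg_loose).cell_names)
        kept_strict = set(filter_cells(two_type_counts, cfg_strict).cell_names)
        assert kept_strict <= kept_loose


class TestNormalize:
    def test_single_gene_closed_form(self):
        expr = _expr([[5.0]])
        out = normalize(expr, PreprocessConfig(normalize_scale=10000))
        assert out.matrix[0, 0] == pytest.approx(np.log1p(10000))

    def test_two_equal_genes_scale_two(self):
        expr = _expr([[1.0], [1.0]])
        out = normalize(expr, PreprocessConfig(normalize_scale=2))
        np.testing.assert_allclose(out.matrix[:, 0], np.log(2.0))

    def test_matches_entrywise_scalar_oracle(self):
        mat = np.array([[1.0, 4.0], [2.0, 0.0], [3.0, 6.0]])
        expr = _expr(mat)
        cfg = PreprocessConfig(normalize_scale=100.0)
        out = normalize(expr, cfg)
        for i in range(3):
            for j in range(2):
                expected = np.log(1.0 + mat[i, j] / mat[:, j].sum() * 100.0)
                assert out.matrix[i, j] == pytest.approx(expected, rel=1e-12)

    def test_column_sums_recover_scale(self, two_type_counts):
        cfg = PreprocessConfig(normalize_scale=1e4)
        out = normalize(two_type_counts, cfg)
        np.testing.assert_allclose(np.expm1(out.matrix).sum(axis=0), 1e4, rtol=1e-9)

    def test_zero_total_cell_errors(self):
        expr = _expr([[1.0, 0.0]])
        with pytest.raises(ValueError, match="zero total"):
            normalize(expr, PreprocessConfig())


class TestSelectHVG:
    def test_variable_gene_beats_constant(self):
        expr = _expr([[3, 3, 3, 3], [1, 5, 0, 6]], genes=["const", "vari"])
        assert select_hvg(expr, PreprocessConfig(n_hvg=2))[:1] == ["vari"]

    def test_tie_break_is_lexicographic(self):
        expr = _expr([[1, 3], [1, 3]], genes=["B", "A"])
        cfg = PreprocessConfig(n_hvg=2)
        assert select_hvg(expr, cfg)[0] == "A"

    def test_matches_brute_force_dispersion_sort(self):
        rng = np.random.default_rng(3)
        mat = rng.gamma(2.0, 1.0, size=(10, 12))
        expr = _expr(mat)
        got = select_hvg(expr, PreprocessConfig(n_hvg=3))
        disp = {
            g: mat[i].var() / mat[i].mean() for i, g in enumerate(expr.gene_names)
        }
        expected = sorted(expr.gene_names, key=lambda g: (-disp[g], g))[:3]
        assert got == expected

    def test_n_hvg_above_gene_count_warns_and_returns_all(self, toy_expression):
        with pytest.warns(UserWarning, match="returning all genes"):
            got = select_hvg(toy_expression, PreprocessConfig(n_hvg=100))
        assert sorted(got) == sorted(toy_expression.gene_names)

    def test_stable_under_cell_permutation(self, two_type_counts):
        cfg = PreprocessConfig(n_hvg=5)
        base = select_hvg(two_type_counts, cfg)
        perm = np.random.default_rng(0).permutation(two_type_counts.n_cells)
        shuffled = two_type_counts.subset_cells(perm)
        assert select_hvg(shuffled, cfg) == base

    def test_force_include_keeps_lr_genes(self):
        expr = _expr([[3, 3, 3], [1, 9, 2], [0, 8, 1]], genes=["flat", "v1", "v2"])
        got = select_hvg(expr, PreprocessConfig(n_hvg=2), force_include=["flat"])
        assert "flat" in got and len(got) == 2


class TestMeanByType:
    def test_simple_means(self):
        mat = np.array([[2.0, 4.0, 7.0]])
        expr = _expr(mat, types={"c0": "A", "c1": "A", "c2": "B"})
        u_a, u_b = mean_by_type(expr, "A", "B")
        assert u_a[0] == 3.0 and u_b[0] == 7.0

    def test_singleton_type_mean_is_cell_value(self):
        mat = np.array([[2.0, 9.0]])
        expr = _expr(mat, types={"c0": "A", "c1": "B"})
        _, u_b = mean_by_type(expr, "A", "B")
        assert u_b[0] == 9.0

    def test_matches_per_gene_loop_oracle(self, toy_expression):
        u_a, u_b = mean_by_type(toy_expression, "A", "B")
        for gi in range(toy_expression.n_genes):
            vals_a = [
                toy_expression.matrix[gi, ci]
                for ci, c in enumerate(toy_expression.cell_names)
                if toy_expression.cell_types[c] == "A"
            ]
            assert u_a[gi] == pytest.approx(np.mean(vals_a))

    def test_invariant_to_cell_ordering(self, toy_expression):
        u_a, u_b = mean_by_type(toy_expression, "A", "B")
        perm = np.array([5, 2, 0, 4, 1, 3])
        u_a2, u_b2 = mean_by_type(toy_expression.subset_cells(perm), "A", "B")
        np.testing.assert_allclose(u_a, u_a2)
        np.testing.assert_allclose(u_b, u_b2)

    def test_unknown_label_lists_available(self, toy_expression):
        with pytest.raises(KeyError, match="available: A, B"):
            mean_by_type(toy_expression, "A", "Z")


def test_config_invariants():
    with pytest.raises(ValueError):
        PreprocessConfig(n_hvg=1)
    with pytest.raises(ValueError):
        PreprocessConfig(max_mito_fraction=1.5)
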