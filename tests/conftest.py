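import numpy as np
import pytest

from scsdne import AnnotatedExpression, LRDatabase


@pytest.fixture
def toy_expression() -> AnnotatedExpression:
    """4 genes x 6 cells, two cell types, hand-sized for loop oracles."""
    rng = np.random.default_rng(42)
    mat = rng.integers(0, 8, size=(4, 6)).astype(float)
    genes = ["GA", "GB", "GC", "GD"]
    cells = [f"c{i}" for i in range(6)]
    types = {c: ("A" if i < 3 else "B") for i, c in enumerate(cells)}
    return AnnotatedExpression(mat, genes, cells, types)


@pytest.fixture
def tiny_lrdb() -> LRDatabase:
    return LRDatabase((("GA", "GC"), ("GB", "GD")))


@pytest.fixture
def two_type_counts() -> AnnotatedExpression:
    """Deterministic mid-size count matrix (20 genes x 40 cells, 2 types)."""
    rng = np.random.default_rng(7)
    mat = rng.poisson(2.0, size=(20, 40)).astype(float)
    genes = [f"g{i:02d}" for i in range(20)]
    cells = [f"cell{i:02d}" for i in range(40)]
    types = {c: ("A" if i < 20 else "B") for i, c in enumerate(cells)}
    return AnnotatedExpression(mat, genes, cells, types)
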