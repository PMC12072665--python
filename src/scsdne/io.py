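"""Readers and writers for L-R databases, expression matrices and result tables.

The on-disk dialects are deliberately plain: headered TSV for the
ligand-receptor database and annotations, Matrix Market or dense delimited
text for expression, TSV for interaction calls. Ligand-receptor pairs are
directed (ligand in the sender type, receptor in the receiver type) and are
modelled at gene-symbol level; subunit complexes are not represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

__all__ = [
    "LRDatabase",
    "AnnotatedExpression",
    "InteractionCall",
    "read_lrdb",
    "default_lrdb",
    "read_expression",
    "write_interactions",
    "read_interactions",
]

_DATA_DIR = Path(__file__).parent / "data"

#: fixed decimal format for numeric result columns (6 significant digits)
_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class LRDatabase:
    """A curated set of directed ligand -> receptor gene-symbol pairs."""

    pairs: tuple[tuple[str, str], ...]
    sources: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError("gene symbols must be non-empty strings")
            if (lig, rec) in seen:
                raise ValueError(f"duplicate pair ({lig}, {rec})")
            seen.add((lig, rec))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in set(self.pairs)

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.pairs)

    def restrict(self, genes: Iterable[str]) -> "LRDatabase":
        """Keep only pairs whose ligand and receptor are both in *genes*."""
        genes = set(genes)
        kept = tuple(p for p in self.pairs if p[0] in genes and p[1] in genes)
        return LRDatabase(kept, {p: self.sources[p] for p in kept if p in self.sources})


@dataclass
class AnnotatedExpression:
    """A genes x cells expression matrix with one cell-type label per cell.

    ``matrix`` holds non-negative reals (raw counts or normalized values);
    rows follow ``gene_names``, columns follow ``cell_names``.
    """

    matrix: np.ndarray
    gene_names: list[str]
    cell_names: list[str]
    cell_types: dict[str, str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        if self.matrix.shape != (len(self.gene_names), len(self.cell_names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.cell_names)} cells"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique (collapse duplicates first)")
        if len(set(self.cell_names)) != len(self.cell_names):
            raise ValueError("cell names must be unique")
        if np.isnan(self.matrix).any():
            raise ValueError("expression matrix contains NaN")
        if (self.matrix < 0).any():
            raise ValueError("expression matrix contains negative entries")
        missing = [c for c in self.cell_names if c not in self.cell_types]
        if missing:
            raise ValueError(f"unannotated cells: {', '.join(missing)}")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def type_labels(self) -> list[str]:
        """Distinct cell-type labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.cell_names:
            seen.setdefault(self.cell_types[c], None)
        return list(seen)

    def cells_of_type(self, label: str) -> np.ndarray:
        """Column indices of cells annotated with *label*."""
        idx = np.array(
            [i for i, c in enumerate(self.cell_names) if self.cell_types[c] == label],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(
                f"unknown cell type {label!r}; available: {', '.join(self.type_labels())}"
            )
        return idx

    def subset_genes(self, genes: Sequence[str]) -> "AnnotatedExpression":
        index = {g: i for i, g in enumerate(self.gene_names)}
        try:
            rows = [index[g] for g in genes]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not present") from None
        return AnnotatedExpression(
            self.matrix[rows, :], list(genes), list(self.cell_names), dict(self.cell_types)
        )

    def subset_cells(self, columns: np.ndarray) -> "AnnotatedExpression":
        names = [self.cell_names[i] for i in columns]
        return AnnotatedExpression(
            self.matrix[:, columns], list(self.gene_names), names, dict(self.cell_types)
        )


@dataclass(frozen=True)
class InteractionCall:
    """One scored ligand-receptor pair between a sender and a receiver type."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    crosstalk_score: float
    latent_distance: float
    p_value: float
    significant: bool


def read_lrdb(
    path: str | Path,
    allow_self_pairs: bool = False,
    ignore_case: bool = False,
) -> LRDatabase:
    """Read a ligand-receptor database from a headered TSV.

    Expected columns: ``ligand``, ``receptor``, optional ``source``.
    Duplicate (ligand, receptor) rows are dropped, keeping first occurrence;
    insertion order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[tuple[str, str]] = []
    sources: dict[tuple[str, str], str] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
        try:
            i_lig, i_rec = cols.index("ligand"), cols.index("receptor")
        except ValueError:
            raise ValueError(
                f"{path}: header must contain 'ligand' and 'receptor' columns, got {cols}"
            ) from None
        i_src = cols.index("source") if "source" in cols else None
        n_rows = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(i_lig, i_rec):
                raise ValueError(f"{path}:{lineno}: too few columns")
            lig, rec = fields[i_lig].strip(), fields[i_rec].strip()
            if not lig or not rec:
                raise ValueError(f"{path}:{lineno}: empty ligand or receptor field")
            if ignore_case:
                lig, rec = lig.upper(), rec.upper()
            if lig == rec and not allow_self_pairs:
                raise ValueError(
                    f"{path}:{lineno}: self-pair ({lig}, {rec}) rejected "
                    "(pass allow_self_pairs=True to keep)"
                )
            n_rows += 1
            if (lig, rec) in seen:
                continue
            seen.add((lig, rec))
            pairs.append((lig, rec))
            if i_src is not None and len(fields) > i_src and fields[i_src].strip():
                sources[(lig, rec)] = fields[i_src].strip()
        if n_rows == 0:
            raise ValueError(f"{path}: no data rows")
    return LRDatabase(tuple(pairs), sources)


def default_lrdb() -> LRDatabase:
    """The small curated L-R database shipped with the package."""
    return read_lrdb(_DATA_DIR / "lrdb.tsv")


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    celltype_path: str | Path = None,
    ignore_case: bool = False,
) -> AnnotatedExpression:
    """Read an expression matrix plus a cell -> type annotation table.

    Two layouts are accepted:

    * Matrix Market (``.mtx``, genes as rows) with one-name-per-line sidecar
      files for genes and cells;
    * dense CSV/TSV with gene names in the first column and cell names in the
      header row (``genes_path``/``cells_path`` ignored).

    The annotation file is a headerless or headered two-column TSV mapping
    every cell id to exactly one type label. Duplicate gene symbols are
    collapsed by summation with a warning.
    """
    matrix_path = Path(matrix_path)
    if celltype_path is None:
        raise ValueError("celltype_path is required")
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires genes_path and cells_path")
        mat = np.asarray(mmread(matrix_path).todense(), dtype=float)
        genes = _read_lines(Path(genes_path))
        cells = _read_lines(Path(cells_path))
    else:
        sep = "," if matrix_path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
    if ignore_case:
        genes = [g.upper() for g in genes]
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    if (mat < 0).any():
        raise ValueError("negative entries in expression matrix")

    # collapse duplicate gene symbols by summation (deterministic, order-independent)
    if len(set(genes)) != len(genes):
        order: dict[str, int] = {}
        for g in genes:
            order.setdefault(g, len(order))
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        warnings.warn(f"collapsing duplicate gene symbols by sum: {', '.join(dupes)}")
        collapsed = np.zeros((len(order), mat.shape[1]))
        for row, g in enumerate(genes):
            collapsed[order[g], :] += mat[row, :]
        mat, genes = collapsed, list(order)

    ann = pd.read_csv(celltype_path, sep="\t", header=None, dtype=str, comment="#")
    if ann.shape[1] < 2:
        raise ValueError(f"{celltype_path}: annotation needs >= 2 columns (cell, type)")
    # tolerate a header row
    if str(ann.iloc[0, 0]).lower() in {"cell", "cell_id", "barcode"}:
        ann = ann.iloc[1:]
    cell_types = dict(zip(ann.iloc[:, 0].str.strip(), ann.iloc[:, 1].str.strip()))
    missing = [c for c in cells if c not in cell_types]
    if missing:
        raise ValueError(f"unannotated cells: {', '.join(missing)}")
    return AnnotatedExpression(mat, genes, cells, {c: cell_types[c] for c in cells})


_COLUMNS = [
    "ligand",
    "receptor",
    "sender_type",
    "receiver_type",
    "crosstalk_score",
    "latent_distance",
    "p_value",
    "significant",
]


def write_interactions(calls: Sequence[InteractionCall], path: str | Path) -> None:
    """Write interaction calls as TSV, sorted by p-value then latent distance."""
    rows = sorted(calls, key=lambda c: (c.p_value, c.latent_distance))
    df = pd.DataFrame(
        [
            {
                "ligand": c.ligand,
                "receptor": c.receptor,
                "sender_type": c.sender,
                "receiver_type": c.receiver,
                "crosstalk_score": c.crosstalk_score,
                "latent_distance": c.latent_distance,
                "p_value": c.p_value,
                "significant": str(c.significant).lower(),
            }
            for c in rows
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_interactions(path: str | Path) -> list[InteractionCall]:
    """Re-read a TSV written by :func:`write_interactions`."""
    df = pd.read_csv(path, sep="\t")
    return [
        InteractionCall(
            ligand=str(r.ligand),
            receptor=str(r.receptor),
            sender=str(r.sender_type),
            receiver=str(r.receiver_type),
            crosstalk_score=float(r.crosstalk_score),
            latent_distance=float(r.latent_distance),
            p_value=float(r.p_value),
            significant=str(r.significant).lower() == "true",
        )
        for r in df.itertuples()
    ]
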