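"""Readers and writers for expression matrices and tabular pipeline outputs.

The in-memory container is :class:`ExpressionMatrix`: a sparse cells × genes
raw-count matrix with an optional log-normalized layer of the same shape.
All readers normalize orientation to cells × genes regardless of the on-disk
layout (the 10x triplet dialect stores genes as rows).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "MatrixParseError",
    "read_mtx",
    "read_dense_table",
    "write_mtx",
    "write_dense_table",
    "write_class_profile",
    "write_combination_table",
    "read_subset_counts",
]


class FormatError(ValueError):
    """On-disk data does not match the expected file layout."""


class MatrixParseError(ValueError):
    """A matrix file contains entries that cannot be parsed as numbers."""


@dataclass
class ExpressionMatrix:
    """Sparse cells × genes count matrix with an optional normalized layer.

    Parameters
    ----------
    cell_ids, gene_ids
        Unique row and column labels.
    counts
        Non-negative raw counts, shape ``(len(cell_ids), len(gene_ids))``.
    normalized
        Optional same-shape log-normalized values; must share the zero
        pattern of ``counts``.
    meta
        Free-form string annotations (species, stage, source, ...).
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix
    normalized: sp.csr_matrix | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.normalized is not None:
            self.normalized = sp.csr_matrix(self.normalized)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for kind, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise FormatError(f"duplicate {kind} ids: {dupes[:5]}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.normalized is not None:
            if self.normalized.shape != self.counts.shape:
                raise FormatError("normalized layer shape differs from counts")
            a = self.counts.astype(bool)
            b = self.normalized.astype(bool)
            if (a != b).nnz:
                raise ValueError("normalized layer zero pattern differs from counts")

    # -- conveniences ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def layer(self, name: str) -> sp.csr_matrix:
        """Return ``counts`` or ``normalized`` by name."""
        if name == "counts":
            return self.counts
        if name == "normalized":
            if self.normalized is None:
                raise ValueError("matrix has no normalized layer; run log_normalize first")
            return self.normalized
        raise ValueError(f"unknown layer {name!r}; expected 'counts' or 'normalized'")

    def gene_index(self, gene_id: str, case_insensitive: bool = False) -> int | None:
        """Column index of ``gene_id``, or None if absent."""
        if not hasattr(self, "_gene_lookup") or self._gene_lookup_ci != case_insensitive:
            key = (lambda s: s.lower()) if case_insensitive else (lambda s: s)
            lut: dict[str, int] = {}
            for i, g in enumerate(self.gene_ids):
                lut.setdefault(key(g), i)
            self._gene_lookup = lut
            self._gene_lookup_ci = case_insensitive
        key = gene_id.lower() if case_insensitive else gene_id
        return self._gene_lookup.get(key)

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (normalized layer preserved)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=self.cell_ids),
            var=pd.DataFrame(index=self.gene_ids),
        )
        if self.normalized is not None:
            adata.layers["normalized"] = self.normalized.copy()
        adata.uns.update(self.meta)
        return adata

    @classmethod
    def from_anndata(cls, adata, normalized_layer: str | None = "normalized"):
        norm = None
        if normalized_layer and normalized_layer in adata.layers:
            norm = sp.csr_matrix(adata.layers[normalized_layer])
        return cls(
            cell_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            counts=sp.csr_matrix(adata.X),
            normalized=norm,
        )


# ---------------------------------------------------------------------------
# readers


def _read_label_column(path: Path) -> list[str]:
    """First column of a headerless TSV/CSV label table (10x barcodes/features)."""
    labels = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            labels.append(line.split("\t")[0].split(",")[0])
    return labels


def _find_one(directory: Path, patterns: list[str], what: str) -> Path:
    for pat in patterns:
        hits = sorted(directory.glob(pat))
        if hits:
            return hits[0]
    raise FormatError(f"no {what} file found in {directory} (tried {patterns})")


def _locate_bad_line(path: Path) -> int | None:
    """Line number (1-based) of the first non-numeric coordinate entry."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("%"):
                continue
            for tok in line.split():
                try:
                    float(tok)
                except ValueError:
                    return lineno
    return None


def _aggregate_duplicate_genes(
    counts: sp.csr_matrix, gene_ids: list[str]
) -> tuple[sp.csr_matrix, list[str]]:
    """Sum columns sharing a gene ID, preserving first-occurrence order."""
    if len(set(gene_ids)) == len(gene_ids):
        return counts, gene_ids
    order: dict[str, int] = {}
    for g in gene_ids:
        order.setdefault(g, len(order))
    dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
    logger.warning("duplicate gene ids aggregated by summation: %s", dupes)
    warnings.warn(f"duplicate gene ids aggregated by summation: {dupes}", stacklevel=3)
    # column-aggregation via a sparse indicator matrix: (cells x g_old) @ (g_old x g_new)
    rows = np.arange(len(gene_ids))
    cols = np.array([order[g] for g in gene_ids])
    agg = sp.csr_matrix(
        (np.ones(len(gene_ids)), (rows, cols)), shape=(len(gene_ids), len(order))
    )
    return sp.csr_matrix(counts @ agg), list(order)


def read_mtx(directory: str | Path) -> ExpressionMatrix:
    """Read a 10x-style Matrix Market triplet directory.

    The directory must contain a ``.mtx`` coordinate file plus one-column
    barcode and feature tables. Orientation is detected by matching matrix
    dimensions against the label-table lengths: the 10x dialect stores genes
    as rows and is transposed to cells × genes on load. Duplicate gene IDs
    are aggregated by summation with a warning.
    """
    directory = Path(directory)
    mtx_path = _find_one(directory, ["*.mtx", "*.mtx.gz"], "Matrix Market")
    barcodes_path = _find_one(directory, ["barcodes*"], "barcode")
    features_path = _find_one(directory, ["features*", "genes*"], "feature")

    cells = _read_label_column(barcodes_path)
    genes = _read_label_column(features_path)
    try:
        mat = scipy.io.mmread(mtx_path)
    except ValueError as exc:
        lineno = _locate_bad_line(mtx_path)
        where = f" at line {lineno}" if lineno else ""
        raise MatrixParseError(f"non-numeric entry in {mtx_path}{where}: {exc}") from exc

    mat = sp.csr_matrix(mat)
    nr, nc = mat.shape
    if nr == len(genes) and nc == len(cells):
        mat = sp.csr_matrix(mat.T)  # genes-as-rows (10x dialect)
    elif nr == len(cells) and nc == len(genes):
        pass
    else:
        raise FormatError(
            f"{mtx_path} has shape {mat.shape} but {barcodes_path.name} lists "
            f"{len(cells)} barcodes and {features_path.name} lists {len(genes)} features"
        )
    mat, genes = _aggregate_duplicate_genes(mat, genes)
    return ExpressionMatrix(cell_ids=cells, gene_ids=genes, counts=mat)


def read_dense_table(
    path: str | Path, orientation: str = "cells-as-rows", sep: str | None = None
) -> ExpressionMatrix:
    """Read a labelled dense delimited table as an ExpressionMatrix.

    ``orientation`` is ``"cells-as-rows"`` or ``"genes-as-rows"``; the latter
    is transposed on load. The delimiter is sniffed unless ``sep`` is given.
    """
    if orientation not in ("cells-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"malformed table {path}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise MatrixParseError(f"non-numeric column(s) in {path}: {bad}")
    if df.isna().any().any():
        raise MatrixParseError(f"missing values (ragged rows?) in {path}")
    if (df.values < 0).any():
        raise ValueError(f"negative expression values in {path}")
    if orientation == "genes-as-rows":
        df = df.T
    counts = sp.csr_matrix(df.values)
    counts, gene_ids = _aggregate_duplicate_genes(counts, [str(g) for g in df.columns])
    return ExpressionMatrix(
        cell_ids=[str(c) for c in df.index], gene_ids=gene_ids, counts=counts
    )


# ---------------------------------------------------------------------------
# writers


def write_mtx(matrix: ExpressionMatrix, directory: str | Path) -> None:
    """Write a 10x-style triplet directory (genes as rows, the common dialect)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = sp.coo_matrix(matrix.counts.T)
    if matrix.counts.nnz == 0 or np.allclose(matrix.counts.data % 1, 0):
        data = data.astype(np.int64)
        scipy.io.mmwrite(directory / "matrix.mtx", data, field="integer")
    else:
        scipy.io.mmwrite(directory / "matrix.mtx", data)
    (directory / "barcodes.tsv").write_text(
        "".join(f"{c}\n" for c in matrix.cell_ids), encoding="utf-8"
    )
    (directory / "features.tsv").write_text(
        "".join(f"{g}\n" for g in matrix.gene_ids), encoding="utf-8"
    )


def write_dense_table(
    matrix: ExpressionMatrix, path: str | Path, layer: str = "counts"
) -> None:
    dense = matrix.layer(layer).toarray()
    df = pd.DataFrame(dense, index=matrix.cell_ids, columns=matrix.gene_ids)
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def write_class_profile(profile, path: str | Path) -> None:
    """Write per-cell class membership as TSV (cell_id, then one 0/1 column per class)."""
    df = pd.DataFrame(
        profile.membership.astype(int),
        index=pd.Index(profile.cell_ids, name="cell_id"),
        columns=profile.class_names,
    )
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def write_combination_table(counts, path: str | Path) -> None:
    """Write a combination-lattice table as TSV.

    Columns: subset label, exclusive, inclusive, pct_exclusive, pct_inclusive.
    Rows sorted by descending exclusive count, ties broken lexicographically on
    the label. Subsets with zero exclusive count are omitted unless explicitly
    present in the counts (e.g. a zero implied by a printed inclusive table);
    the empty set is always reported.
    """
    from .coexpression import subset_label

    rows = []
    subsets = set(counts.exclusive) | {frozenset()}
    for s in subsets:
        excl = counts.exclusive.get(s, 0)
        incl = counts.inclusive_count(s)
        label = subset_label(s, counts.class_names)
        if counts.total_cells > 0:
            pe = f"{100.0 * excl / counts.total_cells:.6g}"
            pi = f"{100.0 * incl / counts.total_cells:.6g}"
        else:
            pe = pi = ""
        rows.append((label, excl, incl, pe, pi))
    rows.sort(key=lambda r: (-r[1], r[0]))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("subset\texclusive\tinclusive\tpct_exclusive\tpct_inclusive\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_subset_counts(path: str | Path, column: str = "inclusive") -> dict[str, int]:
    """Read subset counts from a combination table (or any subset/count TSV).

    Accepts the full five-column layout written by :func:`write_combination_table`
    or a two-column ``subset<TAB>count`` table. Returns labels → counts.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if column in df.columns:
        values = df[column]
    elif df.shape[1] == 2:
        values = df.iloc[:, 1]
    else:
        raise FormatError(f"{path} has no {column!r} column and is not two-column")
    labels = df.iloc[:, 0].fillna("")
    return {str(lbl): int(v) for lbl, v in zip(labels, values)}
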