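"""Count normalization and boolean threshold gating over gene expression.

Cells are selected the way scRNA-seq pipelines conventionally select neurons:
normalize counts, then keep cells satisfying a boolean rule over per-gene
expression thresholds such as ``"nSyb > 1 and elav > 1 and Syt1 > 1"``.

Normalization is the standard per-cell log transform: each count ``c`` in a
cell with total ``T`` becomes ``ln(1 + c * scale_factor / T)`` with a default
scale factor of 10,000. The natural logarithm is used (the convention of this
normalization); thresholds in the shipped rules apply to this layer.

Rule grammar::

    atom := GENE CMP NUMBER           CMP in {">", ">=", "≥"}
    expr := atom | expr and expr | expr or expr | not expr | (expr)

with standard precedence (NOT > AND > OR), left associative. A comma is
accepted as a synonym for the adjacent keyword connective, so
``"a > 1, b > 1 and c > 1"`` parses as a three-way AND.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GatingRule",
    "Atom",
    "And",
    "Or",
    "Not",
    "RuleSyntaxError",
    "log_normalize",
    "parse_gating_rule",
    "evaluate_gating_rule",
    "subset_cells",
    "write_mask",
]


# ---------------------------------------------------------------------------
# normalization


def log_normalize(matrix: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Return a new matrix carrying a log-normalized layer.

    ``normalized[i, g] = ln(1 + counts[i, g] * scale_factor / T_i)`` where
    ``T_i`` is cell *i*'s total count. Cells with zero total get all-zero
    normalized rows (degenerate inputs flow through rather than erroring).
    The counts layer is left untouched; zeros stay zeros, and within a cell
    the transform is strictly increasing in the count.
    """
    if not scale_factor > 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor}")
    counts = sp.csr_matrix(matrix.counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    norm = counts.copy()
    if norm.nnz:
        row_of_entry = np.repeat(np.arange(matrix.n_cells), np.diff(norm.indptr))
        t = totals[row_of_entry]
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(t > 0, norm.data * (scale_factor / np.where(t > 0, t, 1.0)), 0.0)
        norm.data = np.log1p(scaled)
        norm.eliminate_zeros()
    return ExpressionMatrix(
        cell_ids=list(matrix.cell_ids),
        gene_ids=list(matrix.gene_ids),
        counts=matrix.counts,
        normalized=norm,
        meta=dict(matrix.meta),
    )


# ---------------------------------------------------------------------------
# rule AST


@dataclass(frozen=True)
class Atom:
    gene: str
    cmp: str          # ">" or ">="
    threshold: float

    def __str__(self) -> str:
        return f"{self.gene} {self.cmp} {self.threshold:g}"


@dataclass(frozen=True)
class And:
    children: tuple

    def __str__(self) -> str:
        return " and ".join(_paren(c, (Or,)) for c in self.children)


@dataclass(frozen=True)
class Or:
    children: tuple

    def __str__(self) -> str:
        return " or ".join(str(c) for c in self.children)


@dataclass(frozen=True)
class Not:
    child: object

    def __str__(self) -> str:
        return f"not {_paren(self.child, (And, Or))}"


def _paren(node, wrap_types) -> str:
    s = str(node)
    return f"({s})" if isinstance(node, wrap_types) else s


@dataclass(frozen=True)
class GatingRule:
    """A parsed boolean expression tree over (gene, comparator, threshold) atoms."""

    root: object
    source: str = ""

    @property
    def genes(self) -> list[str]:
        out: list[str] = []

        def walk(node):
            if isinstance(node, Atom):
                if node.gene not in out:
                    out.append(node.gene)
            elif isinstance(node, Not):
                walk(node.child)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def __str__(self) -> str:
        return str(self.root)


# ---------------------------------------------------------------------------
# parser


class RuleSyntaxError(ValueError):
    """A gating rule string does not match the grammar."""


_TOKEN_RE = re.compile(r"\s*(>=|≥|>|\(|\)|,|[^\s(),]+)")
_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_KEYWORDS = {"and", "or", "not"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """Yield (kind, value, position) triples. Kinds: CMP LPAR RPAR COMMA AND OR NOT NUMBER GENE."""
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            break
        tok = m.group(1)
        at = m.start(1)
        if tok in (">", ">=", "≥"):
            tokens.append(("CMP", ">=" if tok in (">=", "≥") else ">", at))
        elif tok == "(":
            tokens.append(("LPAR", tok, at))
        elif tok == ")":
            tokens.append(("RPAR", tok, at))
        elif tok == ",":
            tokens.append(("COMMA", tok, at))
        elif tok.lower() in _KEYWORDS:
            tokens.append((tok.lower().upper(), tok, at))
        elif _NUMBER_RE.match(tok):
            tokens.append(("NUMBER", tok, at))
        else:
            tokens.append(("GENE", tok, at))
        pos = m.end()
    return tokens


def _resolve_commas(tokens: list[tuple[str, str, int]]) -> list[tuple[str, str, int]]:
    """Replace COMMA tokens with the adjacent keyword connective.

    Each comma adopts the next explicit AND/OR at the same paren depth; if
    none follows, the nearest preceding one; failing both, AND.
    """
    depth_at = []
    depth = 0
    for kind, _, _ in tokens:
        if kind == "RPAR":
            depth -= 1
        depth_at.append(depth)
        if kind == "LPAR":
            depth += 1
    out = list(tokens)
    for i, (kind, _, at) in enumerate(tokens):
        if kind != "COMMA":
            continue
        repl = None
        for j in range(i + 1, len(tokens)):
            if depth_at[j] < depth_at[i]:
                break
            if depth_at[j] == depth_at[i] and tokens[j][0] in ("AND", "OR"):
                repl = tokens[j][0]
                break
        if repl is None:
            for j in range(i - 1, -1, -1):
                if depth_at[j] < depth_at[i]:
                    break
                if depth_at[j] == depth_at[i] and tokens[j][0] in ("AND", "OR"):
                    repl = tokens[j][0]
                    break
        out[i] = (repl or "AND", "and" if (repl or "AND") == "AND" else "or", at)
    return out


class _Parser:
    def __init__(self, tokens: list[tuple[str, str, int]], source: str):
        self.tokens = tokens
        self.source = source
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        if self.i >= len(self.tokens):
            raise RuleSyntaxError(
                f"unexpected end of rule at position {len(self.source)}: {self.source!r}"
            )
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def error(self, msg: str) -> RuleSyntaxError:
        at = self.tokens[self.i][2] if self.i < len(self.tokens) else len(self.source)
        return RuleSyntaxError(f"{msg} at position {at}: {self.source!r}")

    def parse_or(self):
        children = [self.parse_and()]
        while self.peek() == "OR":
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self):
        children = [self.parse_not()]
        while self.peek() == "AND":
            self.next()
            children.append(self.parse_not())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_not(self):
        if self.peek() == "NOT":
            self.next()
            return Not(self.parse_not())
        return self.parse_primary()

    def parse_primary(self):
        kind = self.peek()
        if kind == "LPAR":
            self.next()
            node = self.parse_or()
            if self.peek() != "RPAR":
                raise self.error("expected ')'")
            self.next()
            return node
        if kind in ("GENE", "NUMBER"):
            # a NUMBER in gene position is a gene whose name looks numeric
            _, gene, _ = self.next()
            if self.peek() != "CMP":
                raise self.error(f"expected comparator after gene {gene!r}")
            _, cmp_, _ = self.next()
            if self.peek() != "NUMBER":
                raise self.error(f"expected numeric threshold after {gene!r} {cmp_}")
            _, num, _ = self.next()
            return Atom(gene=gene, cmp=cmp_, threshold=float(num))
        raise self.error(f"unexpected token")


def parse_gating_rule(text: str) -> GatingRule:
    """Parse a rule string such as ``"Syt1 > 1"`` into a :class:`GatingRule`."""
    tokens = _resolve_commas(_tokenize(text))
    if not tokens:
        raise RuleSyntaxError(f"empty rule: {text!r}")
    parser = _Parser(tokens, text)
    root = parser.parse_or()
    if parser.i != len(tokens):
        raise parser.error("dangling input")
    return GatingRule(root=root, source=text)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_gating_rule(
    matrix: ExpressionMatrix,
    rule: GatingRule | str,
    layer: str = "normalized",
    case_insensitive: bool = False,
) -> np.ndarray:
    """Evaluate a rule per cell, returning a boolean mask of length n_cells.

    Atoms referencing genes absent from the matrix evaluate FALSE with a
    logged warning (panels span genome versions; soft-fail by design).
    """
    if isinstance(rule, str):
        rule = parse_gating_rule(rule)
    values = matrix.layer(layer)

    def ev(node) -> np.ndarray:
        if isinstance(node, Atom):
            idx = matrix.gene_index(node.gene, case_insensitive=case_insensitive)
            if idx is None:
                msg = f"gene {node.gene!r} absent from matrix; atom evaluates FALSE"
                logger.warning(msg)
                warnings.warn(msg, stacklevel=4)
                return np.zeros(matrix.n_cells, dtype=bool)
            col = np.asarray(values[:, idx].todense()).ravel()
            return col > node.threshold if node.cmp == ">" else col >= node.threshold
        if isinstance(node, Not):
            return ~ev(node.child)
        if isinstance(node, And):
            out = ev(node.children[0])
            for c in node.children[1:]:
                out &= ev(c)
            return out
        if isinstance(node, Or):
            out = ev(node.children[0])
            for c in node.children[1:]:
                out |= ev(c)
            return out
        raise TypeError(f"unknown rule node {node!r}")

    return ev(rule.root)


# ---------------------------------------------------------------------------
# subsetting


def subset_cells(
    matrix: ExpressionMatrix, selector: np.ndarray | list[str]
) -> ExpressionMatrix:
    """Row-subset a matrix by boolean mask or explicit cell-ID whitelist.

    Preserves the gene universe and both layers. Whitelist order is kept;
    unknown whitelist IDs are an error naming them. An empty result is legal
    (warning only).
    """
    mask_like = np.asarray(selector)
    if mask_like.dtype == bool:
        if mask_like.shape != (matrix.n_cells,):
            raise ValueError(
                f"mask length {mask_like.shape} does not match {matrix.n_cells} cells"
            )
        idx = np.flatnonzero(mask_like)
        cell_ids = [matrix.cell_ids[i] for i in idx]
    else:
        lut = {c: i for i, c in enumerate(matrix.cell_ids)}
        unknown = [str(c) for c in selector if str(c) not in lut]
        if unknown:
            raise KeyError(f"whitelist cell ids not in matrix: {unknown}")
        idx = np.array([lut[str(c)] for c in selector], dtype=int)
        cell_ids = [str(c) for c in selector]
    if len(idx) == 0:
        warnings.warn("cell subset is empty", stacklevel=2)
        logger.warning("cell subset is empty")
    return ExpressionMatrix(
        cell_ids=cell_ids,
        gene_ids=list(matrix.gene_ids),
        counts=matrix.counts[idx],
        normalized=None if matrix.normalized is None else matrix.normalized[idx],
        meta=dict(matrix.meta),
    )


def write_mask(cell_ids: list[str], mask: np.ndarray, path) -> None:
    """Write a boolean cell mask as two-column TSV (cell_id, bool)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cell_id\tselected\n")
        for cid, m in zip(cell_ids, mask):
            fh.write(f"{cid}\t{bool(m)}\n")
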