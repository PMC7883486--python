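"""Per-cell neurotransmitter class calls and the co-expression combination lattice.

A cell is positive for a class iff ANY of the class's marker genes exceeds the
expression threshold (OR-over-markers, the convention under which a panel like
ChAT/VAChT/ChT defines "cholinergic"). The resulting per-cell class sets are
summarized as subset counts in two conventions:

* exclusive(S): cells whose class set equals S exactly — the conventional
  UpSet bar;
* inclusive(S): cells whose class set contains S — "at least S", the way
  in-text dual counts are usually quoted.

The two are related by the Möbius / inclusion–exclusion transform over the
subset lattice::

    inclusive(S) = Σ_{T ⊇ S} exclusive(T)
    exclusive(S) = Σ_{T ⊇ S} (−1)^{|T\\S|} inclusive(T)

Both conventions are always reported with explicit column names, because
published counts mix them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .panels import ResolvedPanelSet

__all__ = [
    "ClassProfile",
    "CombinationCounts",
    "ConsistencyError",
    "subset_label",
    "parse_subset_label",
    "assign_classes",
    "merge_profile_classes",
    "combination_counts",
    "exclusive_from_inclusive",
    "inclusive_from_exclusive",
    "counts_from_inclusive",
    "binary_expression_matrix",
    "combination_proportions",
    "compare_datasets",
]

EMPTY_LABEL = "(none)"

_MAX_CLASSES = 20  # 2^k lattice; guard against accidental huge panels


class ConsistencyError(ValueError):
    """Subset counts are not realizable by any multiset of cells."""


def subset_label(subset: Iterable[str], class_names: list[str]) -> str:
    """Join class names with "+" in panel-declaration order; empty set → ``(none)``."""
    s = set(subset)
    unknown = s - set(class_names)
    if unknown:
        raise KeyError(f"subset names not in class universe: {sorted(unknown)}")
    ordered = [c for c in class_names if c in s]
    return "+".join(ordered) if ordered else EMPTY_LABEL


def parse_subset_label(label: str) -> frozenset[str]:
    label = label.strip()
    if label in ("", EMPTY_LABEL):
        return frozenset()
    return frozenset(part.strip() for part in label.split("+") if part.strip())


# ---------------------------------------------------------------------------
# per-cell class assignment


@dataclass
class ClassProfile:
    """Boolean cells × classes membership with the call parameters that produced it."""

    cell_ids: list[str]
    class_names: list[str]
    membership: np.ndarray        # bool, shape (n_cells, n_classes)
    threshold: float = 1.0
    layer: str = "normalized"

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.cell_ids), len(self.class_names)):
            raise ValueError(
                f"membership shape {self.membership.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.class_names)} classes"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_subsets(self) -> list[frozenset[str]]:
        """Per-cell positive-class sets, in cell order."""
        names = np.array(self.class_names, dtype=object)
        return [frozenset(names[row]) for row in self.membership]


def assign_classes(
    matrix: ExpressionMatrix,
    resolved: ResolvedPanelSet,
    threshold: float = 1.0,
    layer: str = "normalized",
) -> ClassProfile:
    """Call per-cell class membership: positive iff ANY panel gene > threshold."""
    if not resolved.class_names:
        raise ValueError("resolved panel set has no classes")
    values = matrix.layer(layer)
    membership = np.zeros((matrix.n_cells, len(resolved.class_names)), dtype=bool)
    for j, name in enumerate(resolved.class_names):
        cols = resolved.columns[name]
        sub = values[:, cols]
        membership[:, j] = np.asarray((sub > threshold).sum(axis=1)).ravel() > 0
    return ClassProfile(
        cell_ids=list(matrix.cell_ids),
        class_names=list(resolved.class_names),
        membership=membership,
        threshold=threshold,
        layer=layer,
    )


def merge_profile_classes(
    profile: ClassProfile, groups: Mapping[str, list[str]]
) -> ClassProfile:
    """Merge membership columns by union (e.g. aminergic subtypes → one class)."""
    merged_sources = {c for members in groups.values() for c in members}
    unknown = merged_sources - set(profile.class_names)
    if unknown:
        raise KeyError(f"merge references unknown classes: {sorted(unknown)}")
    names: list[str] = [c for c in profile.class_names if c not in merged_sources]
    cols = [profile.membership[:, profile.class_names.index(c)] for c in names]
    for new_name, members in groups.items():
        idx = [profile.class_names.index(c) for c in members]
        names.append(new_name)
        cols.append(profile.membership[:, idx].any(axis=1))
    return ClassProfile(
        cell_ids=list(profile.cell_ids),
        class_names=names,
        membership=np.column_stack(cols) if cols else np.zeros((profile.n_cells, 0), bool),
        threshold=profile.threshold,
        layer=profile.layer,
    )


# ---------------------------------------------------------------------------
# combination counting


@dataclass
class CombinationCounts:
    """Subset counts of the class-combination lattice in both conventions."""

    class_names: list[str]
    exclusive: dict[frozenset[str], int]
    inclusive: dict[frozenset[str], int] = field(default_factory=dict)
    total_cells: int = 0

    def exclusive_count(self, subset: Iterable[str]) -> int:
        return self.exclusive.get(frozenset(subset), 0)

    def inclusive_count(self, subset: Iterable[str]) -> int:
        subset = frozenset(subset)
        if subset in self.inclusive:
            return self.inclusive[subset]
        if not subset:
            return self.total_cells
        return 0

    def validate(self) -> None:
        if sum(self.exclusive.values()) != self.total_cells:
            raise ConsistencyError("exclusive counts do not sum to total_cells")
        if self.inclusive_count(()) != self.total_cells:
            raise ConsistencyError("inclusive(empty set) must equal total_cells")


def _masks_from_subsets(
    subsets: Iterable[frozenset[str]], class_names: list[str]
) -> np.ndarray:
    order = {c: i for i, c in enumerate(class_names)}
    out = []
    for s in subsets:
        m = 0
        for c in s:
            if c not in order:
                raise KeyError(f"class {c!r} not in class universe {class_names}")
            m |= 1 << order[c]
        out.append(m)
    return np.asarray(out, dtype=np.int64)


def _subset_from_mask(mask: int, class_names: list[str]) -> frozenset[str]:
    return frozenset(c for i, c in enumerate(class_names) if mask >> i & 1)


def _zeta_supersets(values: np.ndarray, k: int) -> np.ndarray:
    """Sum-over-supersets transform: out[S] = Σ_{T ⊇ S} values[T]."""
    out = values.copy()
    for b in range(k):
        bit = 1 << b
        lo = np.flatnonzero((np.arange(1 << k) & bit) == 0)
        out[lo] += out[lo | bit]
    return out


def _moebius_supersets(values: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`_zeta_supersets`: out[S] = Σ_{T ⊇ S} (−1)^{|T\\S|} values[T]."""
    out = values.copy()
    for b in range(k):
        bit = 1 << b
        lo = np.flatnonzero((np.arange(1 << k) & bit) == 0)
        out[lo] -= out[lo | bit]
    return out


def combination_counts(profile: ClassProfile) -> CombinationCounts:
    """Count cells per exact class subset (exclusive) and per contained subset (inclusive).

    One pass over cells: each membership row is packed into a bitmask, masks
    are tallied, and the inclusive map follows by the superset-sum transform
    (exact integer arithmetic).
    """
    k = len(profile.class_names)
    if k > _MAX_CLASSES:
        raise ValueError(f"{k} classes exceeds the {_MAX_CLASSES}-class lattice limit")
    weights = (1 << np.arange(k)).astype(np.int64)
    cell_masks = profile.membership.astype(np.int64) @ weights if k else np.zeros(
        profile.n_cells, dtype=np.int64
    )
    excl_arr = np.bincount(cell_masks, minlength=1 << k).astype(np.int64)
    incl_arr = _zeta_supersets(excl_arr, k)
    exclusive = {
        _subset_from_mask(m, profile.class_names): int(v)
        for m, v in enumerate(excl_arr)
        if v or m == 0
    }
    inclusive = {
        _subset_from_mask(m, profile.class_names): int(v)
        for m, v in enumerate(incl_arr)
        if v or m == 0
    }
    return CombinationCounts(
        class_names=list(profile.class_names),
        exclusive=exclusive,
        inclusive=inclusive,
        total_cells=profile.n_cells,
    )


# ---------------------------------------------------------------------------
# inclusive <-> exclusive transforms


def _normalize_subset_map(
    counts: Mapping, class_names: list[str]
) -> dict[frozenset[str], int]:
    out: dict[frozenset[str], int] = {}
    for key, v in counts.items():
        s = parse_subset_label(key) if isinstance(key, str) else frozenset(key)
        if s in out:
            raise ValueError(f"duplicate subset {subset_label(s, class_names)!r}")
        out[s] = int(v)
    return out


def exclusive_from_inclusive(
    inclusive: Mapping,
    class_names: list[str],
    total_cells: int | None = None,
) -> dict[frozenset[str], int]:
    """Möbius-invert inclusive ("at least S") counts into exclusive ("exactly S") counts.

    Missing subsets are treated as zero. Keys may be frozensets or "+"-joined
    labels. If ``total_cells`` is given, the empty set is included in the
    output (its exclusive count is the cells outside every class); otherwise
    only non-empty subsets are returned, which never need the unknown total.

    Raises :class:`ConsistencyError` if the input is non-monotone or any
    implied exclusive count is negative — i.e. no cell population could have
    produced these numbers.
    """
    inc = _normalize_subset_map(inclusive, class_names)
    k = len(class_names)
    if k > _MAX_CLASSES:
        raise ValueError(f"{k} classes exceeds the {_MAX_CLASSES}-class lattice limit")
    arr = np.zeros(1 << k, dtype=np.int64)
    for s, v in inc.items():
        if v < 0:
            raise ConsistencyError(f"negative inclusive count for {subset_label(s, class_names)!r}")
        arr[_masks_from_subsets([s], class_names)[0]] = v
    if total_cells is not None:
        if frozenset() in inc and inc[frozenset()] != total_cells:
            raise ConsistencyError(
                f"inclusive(empty set)={inc[frozenset()]} contradicts total_cells={total_cells}"
            )
        arr[0] = total_cells
    # monotonicity: S ⊆ T ⇒ inclusive(S) ≥ inclusive(T), checked bitwise,
    # skipping the empty set when the total is unknown
    for b in range(k):
        bit = 1 << b
        lo = np.flatnonzero((np.arange(1 << k) & bit) == 0)
        if total_cells is None and frozenset() not in inc:
            lo = lo[lo != 0]
        bad = lo[arr[lo] < arr[lo | bit]]
        if bad.size:
            s = _subset_from_mask(int(bad[0]), class_names)
            t = _subset_from_mask(int(bad[0]) | bit, class_names)
            raise ConsistencyError(
                f"non-monotone inclusive counts: inclusive({subset_label(s, class_names)!r})="
                f"{arr[bad[0]]} < inclusive({subset_label(t, class_names)!r})={arr[bad[0] | bit]}"
            )
    excl = _moebius_supersets(arr, k)
    include_empty = total_cells is not None or frozenset() in inc
    neg = np.flatnonzero(excl < 0)
    if total_cells is None and frozenset() not in inc:
        neg = neg[neg != 0]
    if neg.size:
        s = _subset_from_mask(int(neg[0]), class_names)
        raise ConsistencyError(
            f"inconsistent inclusive counts: implied exclusive({subset_label(s, class_names)!r}) "
            f"= {excl[neg[0]]} < 0"
        )
    given = {_masks_from_subsets([s], class_names)[0] for s in inc}
    return {
        _subset_from_mask(m, class_names): int(v)
        for m, v in enumerate(excl)
        if (m != 0 or include_empty) and (v or m in given or m == 0)
    }


def inclusive_from_exclusive(
    exclusive: Mapping, class_names: list[str]
) -> dict[frozenset[str], int]:
    """Superset-sum exclusive counts into inclusive counts (exact inverse transform)."""
    exc = _normalize_subset_map(exclusive, class_names)
    k = len(class_names)
    if k > _MAX_CLASSES:
        raise ValueError(f"{k} classes exceeds the {_MAX_CLASSES}-class lattice limit")
    arr = np.zeros(1 << k, dtype=np.int64)
    for s, v in exc.items():
        if v < 0:
            raise ConsistencyError(f"negative exclusive count for {subset_label(s, class_names)!r}")
        arr[_masks_from_subsets([s], class_names)[0]] = v
    incl = _zeta_supersets(arr, k)
    include_empty = frozenset() in exc
    given = {_masks_from_subsets([s], class_names)[0] for s in exc}
    return {
        _subset_from_mask(m, class_names): int(v)
        for m, v in enumerate(incl)
        if (m != 0 and (v or m in given)) or (m == 0 and include_empty)
    }


def counts_from_inclusive(
    inclusive: Mapping, class_names: list[str], total_cells: int | None = None
) -> CombinationCounts:
    """Build a full CombinationCounts object from inclusive counts (convenience)."""
    excl = exclusive_from_inclusive(inclusive, class_names, total_cells=total_cells)
    incl = _normalize_subset_map(inclusive, class_names)
    total = total_cells if total_cells is not None else incl.get(
        frozenset(), sum(v for s, v in excl.items())
    )
    if total_cells is not None:
        incl.setdefault(frozenset(), total_cells)
    return CombinationCounts(
        class_names=list(class_names),
        exclusive=excl,
        inclusive=incl,
        total_cells=int(total),
    )


# ---------------------------------------------------------------------------
# derived tables


def binary_expression_matrix(
    matrix: ExpressionMatrix,
    genes: list[str],
    threshold: float = 1.0,
    layer: str = "normalized",
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """Boolean cells × genes table: TRUE iff expression > threshold.

    The heatmap primitive for receptor co-expression displays. Absent genes
    produce all-FALSE columns with a warning.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    values = matrix.layer(layer)
    cols = {}
    for g in genes:
        idx = matrix.gene_index(g, case_insensitive=case_insensitive)
        if idx is None:
            warnings.warn(f"gene {g!r} absent from matrix; column all FALSE", stacklevel=2)
            cols[g] = np.zeros(matrix.n_cells, dtype=bool)
        else:
            cols[g] = np.asarray(values[:, idx].todense()).ravel() > threshold
    return pd.DataFrame(cols, index=matrix.cell_ids)


def combination_proportions(
    counts: CombinationCounts, which: str = "exclusive"
) -> dict[frozenset[str], float]:
    """Subset counts as percentages of total cells (the cross-dataset unit)."""
    if counts.total_cells <= 0:
        raise ValueError("proportions undefined for zero total cells")
    if which == "exclusive":
        source = counts.exclusive
    elif which == "inclusive":
        source = counts.inclusive if counts.inclusive else {frozenset(): counts.total_cells}
    else:
        raise ValueError(f"which must be 'exclusive' or 'inclusive', got {which!r}")
    return {s: 100.0 * v / counts.total_cells for s, v in source.items()}


def compare_datasets(
    counts_a: CombinationCounts,
    counts_b: CombinationCounts,
    label_a: str = "A",
    label_b: str = "B",
    which: str = "exclusive",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Descriptive per-subset comparison of two datasets on the percentage scale.

    Columns: subset, pct in each dataset, difference (A − B, percentage
    points), ratio (A / B), and a normal-approximation two-proportion
    confidence interval for the difference. The interval is descriptive
    output only — no automated pass/fail is derived from it.
    """
    shared = [c for c in counts_a.class_names if c in counts_b.class_names]
    if not shared:
        raise ValueError(
            f"datasets share no classes: {counts_a.class_names} vs {counts_b.class_names}"
        )
    dropped = (set(counts_a.class_names) | set(counts_b.class_names)) - set(shared)
    if dropped:
        warnings.warn(f"classes not shared by both datasets ignored: {sorted(dropped)}",
                      stacklevel=2)
    from scipy.stats import norm

    z = norm.ppf(0.5 + confidence / 2.0)
    pa = combination_proportions(counts_a, which)
    pb = combination_proportions(counts_b, which)
    subsets = sorted(
        {s for s in (*pa, *pb) if s <= set(shared)},
        key=lambda s: (len(s), subset_label(s, shared)),
    )
    rows = []
    na, nb = counts_a.total_cells, counts_b.total_cells
    for s in subsets:
        a = pa.get(s, 0.0)
        b = pb.get(s, 0.0)
        fa, fb = a / 100.0, b / 100.0
        se = np.sqrt(fa * (1 - fa) / na + fb * (1 - fb) / nb) * 100.0
        rows.append(
            {
                "subset": subset_label(s, shared),
                f"pct_{label_a}": a,
                f"pct_{label_b}": b,
                "difference": a - b,
                "ratio": a / b if b > 0 else np.inf if a > 0 else np.nan,
                "ci_low": (a - b) - z * se,
                "ci_high": (a - b) + z * se,
            }
        )
    return pd.DataFrame(rows)
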