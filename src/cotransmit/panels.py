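"""Species-specific neurotransmitter marker panels.

A panel maps each neurotransmitter class (GABAergic, cholinergic, ...) to the
genes whose expression defines it — vesicular transporters, biosynthetic
enzymes and membrane transporters. Panels are data, not code: every species
ships as a YAML fixture under ``cotransmit/panel_fixtures`` and users can add
species without touching the package.

Marker entries support alias notation ``"primary_id (alias1, alias2)"``; at
resolution time candidates are tried in order against the matrix's gene
universe, so the same panel works across annotation versions that use either
the systematic or the family name.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerGene",
    "MarkerPanelSet",
    "ResolvedPanelSet",
    "ResolutionReport",
    "PanelValidationError",
    "parse_marker_entry",
    "load_panel_config",
    "fixture_panel_path",
    "available_fixture_panels",
    "resolve_panels",
]


class PanelValidationError(ValueError):
    """A panel config violates a structural invariant."""


_ENTRY_RE = re.compile(r"^\s*(?P<primary>[^()]+?)\s*(?:\((?P<aliases>[^()]*)\))?\s*$")


@dataclass(frozen=True)
class MarkerGene:
    """One marker: a primary gene ID plus ordered fallback aliases."""

    primary: str
    aliases: tuple[str, ...] = ()

    @property
    def candidates(self) -> tuple[str, ...]:
        return (self.primary, *self.aliases)

    def __str__(self) -> str:  # round-trips parse_marker_entry
        if self.aliases:
            return f"{self.primary} ({', '.join(self.aliases)})"
        return self.primary


def parse_marker_entry(entry: str) -> MarkerGene:
    """Parse ``"primary (alias1, alias2)"`` notation into a MarkerGene."""
    m = _ENTRY_RE.match(entry)
    if not m or not m.group("primary"):
        raise PanelValidationError(f"unparseable marker entry: {entry!r}")
    aliases = tuple(
        a.strip() for a in (m.group("aliases") or "").split(",") if a.strip()
    )
    return MarkerGene(primary=m.group("primary"), aliases=aliases)


@dataclass
class MarkerPanelSet:
    """Named neurotransmitter classes, each mapping to a non-empty marker list."""

    species: str
    classes: dict[str, list[MarkerGene]]
    provenance: dict[str, str] = field(default_factory=dict)
    gating: str | None = None
    allow_shared: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.classes:
            raise PanelValidationError(f"panel {self.species!r} declares no classes")
        seen_genes: dict[str, str] = {}
        for name, genes in self.classes.items():
            if not genes:
                raise PanelValidationError(
                    f"class {name!r} in panel {self.species!r} has no marker genes"
                )
            for g in genes:
                if g.primary in seen_genes and not self.allow_shared:
                    raise PanelValidationError(
                        f"gene {g.primary!r} appears in both {seen_genes[g.primary]!r} "
                        f"and {name!r}; set allow_shared to permit this"
                    )
                seen_genes.setdefault(g.primary, name)

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)

    def gene_ids(self, class_name: str) -> list[str]:
        """Primary gene IDs of one class, in declaration order."""
        return [g.primary for g in self.classes[class_name]]

    def merge_classes(self, groups: dict[str, list[str]]) -> "MarkerPanelSet":
        """Merge subtype classes into umbrella classes by union of markers.

        ``groups`` maps new class name → list of existing class names (e.g.
        merging serotonergic/dopaminergic/tyraminergic into one aminergic
        category). Classes not mentioned are kept as-is, in original order.
        """
        merged_sources = {c for members in groups.values() for c in members}
        unknown = merged_sources - set(self.classes)
        if unknown:
            raise PanelValidationError(f"merge references unknown classes: {sorted(unknown)}")
        new: dict[str, list[MarkerGene]] = {}
        for name, genes in self.classes.items():
            if name not in merged_sources:
                new[name] = list(genes)
        for name, members in groups.items():
            new[name] = [g for m in members for g in self.classes[m]]
        return MarkerPanelSet(
            species=self.species,
            classes=new,
            provenance=dict(self.provenance),
            gating=self.gating,
            allow_shared=self.allow_shared,
        )


def load_panel_config(path: str | Path, allow_shared: bool = False) -> MarkerPanelSet:
    """Load and validate a YAML (or JSON — valid YAML) panel config.

    Layout::

        species: Caenorhabditis elegans
        classes:
          GABAergic: ["unc-25 (Gad)", "unc-47 (VGAT)", "snf-11 (GAT)"]
        provenance:
          GABAergic: "free-text citation"
        gating: "optional neuron-selection rule string"
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "classes" not in raw:
        raise PanelValidationError(f"{path} is not a panel config (no 'classes' key)")
    classes: dict[str, list[MarkerGene]] = {}
    for name, entries in raw["classes"].items():
        if name in classes:
            raise PanelValidationError(f"duplicate class name {name!r} in {path}")
        if entries is None:
            entries = []
        classes[str(name)] = [parse_marker_entry(str(e)) for e in entries]
    return MarkerPanelSet(
        species=str(raw.get("species", path.stem)),
        classes=classes,
        provenance={str(k): str(v) for k, v in (raw.get("provenance") or {}).items()},
        gating=raw.get("gating"),
        allow_shared=bool(raw.get("allow_shared", allow_shared)),
    )


def fixture_panel_path(name: str) -> Path:
    """Path to a shipped species panel fixture, e.g. ``fixture_panel_path("celegans")``."""
    pkg = resources.files("cotransmit") / "panel_fixtures" / f"{name}.yaml"
    if not pkg.is_file():
        raise FileNotFoundError(
            f"no fixture panel {name!r}; available: {available_fixture_panels()}"
        )
    return Path(str(pkg))


def available_fixture_panels() -> list[str]:
    root = resources.files("cotransmit") / "panel_fixtures"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


# ---------------------------------------------------------------------------
# resolution against a matrix's gene universe


@dataclass
class ResolutionReport:
    """Which panel genes were found in the matrix, per class."""

    missing: dict[str, list[str]]      # class -> marker entries with no match
    unresolvable: list[str]            # classes with zero resolvable genes

    @property
    def fully_resolved(self) -> bool:
        return not any(self.missing.values())


@dataclass
class ResolvedPanelSet:
    """Panel classes mapped to matrix column indices (unresolvable classes dropped)."""

    species: str
    class_names: list[str]             # declaration order, resolvable classes only
    columns: dict[str, list[int]]      # class -> column indices in the matrix
    resolved_genes: dict[str, list[str]]  # class -> gene IDs the columns carry


def resolve_panels(
    panels: MarkerPanelSet,
    matrix: ExpressionMatrix,
    case_insensitive: bool = False,
) -> tuple[ResolvedPanelSet, ResolutionReport]:
    """Map each class's markers to matrix columns; soft-fail on missing genes.

    Each marker's candidates (primary then aliases) are tried in order; the
    first gene ID present in the matrix wins. A class whose markers are all
    absent is excluded from downstream classification with a warning — never
    an error, because panels span genome annotation versions.
    """
    columns: dict[str, list[int]] = {}
    genes: dict[str, list[str]] = {}
    missing: dict[str, list[str]] = {}
    unresolvable: list[str] = []
    for name, markers in panels.classes.items():
        cols: list[int] = []
        ids: list[str] = []
        lost: list[str] = []
        for marker in markers:
            for cand in marker.candidates:
                idx = matrix.gene_index(cand, case_insensitive=case_insensitive)
                if idx is not None:
                    cols.append(idx)
                    ids.append(matrix.gene_ids[idx])
                    break
            else:
                lost.append(str(marker))
        missing[name] = lost
        if cols:
            columns[name] = cols
            genes[name] = ids
        else:
            unresolvable.append(name)
            msg = f"class {name!r}: no marker gene found in matrix; class excluded"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
    resolved = ResolvedPanelSet(
        species=panels.species,
        class_names=[c for c in panels.class_names if c in columns],
        columns=columns,
        resolved_genes=genes,
    )
    return resolved, ResolutionReport(missing=missing, unresolvable=unresolvable)
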