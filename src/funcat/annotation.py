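"""Hierarchical gene-annotation model.

Each gene carries exactly one functional category *path* of depth 1-3,
written with a colon-space delimiter, e.g. ``Proteolysis Proteasome: E3:
F-box``.  Level 1 is a broad physiological or molecular class; levels 2
and 3 refine it.  For counting purposes a gene annotated only at a
shallow depth still contributes at the deeper levels under its deepest
available label, so category counts at every level sum to the size of
the annotated universe (the background for enrichment tests).

Genes with no curated function but whose expression responds to at
least two of six reference stress exposures receive the fallback
category ``Stress response: regulated by multiple stresses``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: default structural delimiter between category levels
PATH_DELIMITER = ": "

#: the six reference stress exposures used for the multi-stress fallback rule
STRESS_DATASETS = (
    "methylmercury",
    "tunicamycin",
    "rotenone",
    "cadmium",
    "ethanol",
    "D-glucose",
)

#: fallback category for unannotated, repeatedly stress-responsive genes
MULTISTRESS_LABEL = "Stress response: regulated by multiple stresses"


@dataclass(frozen=True)
class CategoryPath:
    """One functional annotation path of depth 1-3.

    ``level1`` is always present; ``level3`` requires ``level2``.
    Labels never contain the structural delimiter: the delimiter exists
    only in the rendered text form.
    """

    level1: str
    level2: str | None = None
    level3: str | None = None

    def __post_init__(self) -> None:
        if not self.level1 or not self.level1.strip():
            raise ValueError("level1 label must be non-empty")
        if self.level3 is not None and self.level2 is None:
            raise ValueError("level3 present without level2")
        for label in (self.level1, self.level2, self.level3):
            if label is not None and PATH_DELIMITER in label:
                raise ValueError(
                    f"label {label!r} contains the path delimiter {PATH_DELIMITER!r}"
                )

    @property
    def depth(self) -> int:
        return 1 + (self.level2 is not None) + (self.level3 is not None)

    @classmethod
    def parse(cls, text: str, delimiter: str = PATH_DELIMITER) -> "CategoryPath":
        """Split a rendered category string into its levels.

        A bare colon without a following space is part of a label, not a
        level boundary.  More than three levels is an ambiguous path.
        """
        parts = [p.strip() for p in text.split(delimiter)]
        if len(parts) > 3:
            raise ValueError(f"ambiguous category path (> 3 levels): {text!r}")
        if any(not p for p in parts):
            raise ValueError(f"empty level in category path: {text!r}")
        return cls(*parts)

    def render(self, delimiter: str = PATH_DELIMITER) -> str:
        labels = [l for l in (self.level1, self.level2, self.level3) if l is not None]
        return delimiter.join(labels)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def expand_levels(
    path: CategoryPath, delimiter: str = PATH_DELIMITER
) -> tuple[str, str, str]:
    """Return the level-1/2/3 rollup keys of a path.

    The level-k key is the path truncated to depth k.  Paths shallower
    than k inherit their deepest key, so a depth-1 gene still counts
    once at levels 2 and 3 under its level-1 bucket:

    >>> expand_levels(CategoryPath.parse("Proteolysis Proteasome: E3: F-box"))
    ('Proteolysis Proteasome', 'Proteolysis Proteasome: E3', 'Proteolysis Proteasome: E3: F-box')
    >>> expand_levels(CategoryPath("Metabolism"))
    ('Metabolism', 'Metabolism', 'Metabolism')
    """
    k1 = path.level1
    k2 = k1 if path.level2 is None else k1 + delimiter + path.level2
    k3 = k2 if path.level3 is None else k2 + delimiter + path.level3
    return (k1, k2, k3)


class AnnotationTable:
    """Gene -> :class:`CategoryPath` mapping defining the background universe.

    Treated as immutable after construction; operations that change
    annotations return a new table.  Rollup keys and per-level
    background counts are cached because enrichment scans reuse them
    heavily.
    """

    def __init__(self, entries: Mapping[str, CategoryPath]):
        self._entries: dict[str, CategoryPath] = dict(entries)
        self._expanded: dict[str, tuple[str, str, str]] | None = None
        self._bg_counts: dict[int, dict[str, int]] = {}

    @property
    def entries(self) -> Mapping[str, CategoryPath]:
        return self._entries

    @property
    def universe_size(self) -> int:
        return len(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._entries == other._entries

    @property
    def expanded_keys(self) -> Mapping[str, tuple[str, str, str]]:
        """Cached gene -> (level-1 key, level-2 key, level-3 key)."""
        if self._expanded is None:
            self._expanded = {
                g: expand_levels(p) for g, p in self._entries.items()
            }
        return self._expanded

    def to_frame(self) -> pd.DataFrame:
        """Two-column frame (gene_id, category), sorted by gene id."""
        rows = sorted(
            (g, p.render()) for g, p in self._entries.items()
        )
        return pd.DataFrame(rows, columns=["gene_id", "category"])


def parse_annotation_table(
    source: str | Path | pd.DataFrame,
    id_column: str = "gene_id",
    category_column: str = "category",
    delimiter: str = PATH_DELIMITER,
) -> AnnotationTable:
    """Read an annotation table from delimited text (or a frame).

    Each row maps one gene id to one category path; the path text is
    split into 1-3 levels on ``delimiter`` with per-level whitespace
    stripping.  Duplicate ids, empty category cells and paths deeper
    than three levels are errors.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    for col in (id_column, category_column):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    entries: dict[str, CategoryPath] = {}
    for row_idx, (gene, cat) in enumerate(
        zip(df[id_column], df[category_column]), start=1
    ):
        gene = str(gene).strip()
        if pd.isna(cat) or not str(cat).strip():
            raise ValueError(f"empty category cell at row {row_idx} (gene {gene!r})")
        if gene in entries:
            raise ValueError(f"duplicate gene id {gene!r}")
        entries[gene] = CategoryPath.parse(str(cat), delimiter=delimiter)
    return AnnotationTable(entries)


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    """Write as TSV, rows sorted by gene id (stable on re-write)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


class StressEvidenceMatrix:
    """Boolean gene x stress-dataset matrix ("expression changed").

    The thresholds that produced the booleans are upstream of this
    tool; cells are taken at face value.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.columns.duplicated().any():
            raise ValueError("stress dataset column names must be unique")
        if frame.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        try:
            frame = frame.astype(bool) if frame.isin([0, 1, True, False]).all().all() else None
        except TypeError:
            frame = None
        if frame is None:
            raise ValueError("every evidence cell must be boolean (or 0/1)")
        self.frame = frame

    @property
    def stresses(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def n_changed(self) -> pd.Series:
        """Number of stress datasets in which each gene changed."""
        return self.frame.sum(axis=1)


@dataclass
class MultistressReport:
    """Outcome of applying the multi-stress fallback rule."""

    n_assigned: int
    assigned_genes: tuple[str, ...] = field(default_factory=tuple)


def assign_multistress_category(
    table: AnnotationTable,
    evidence: StressEvidenceMatrix,
    min_stresses: int = 2,
    label: CategoryPath = CategoryPath("Stress response", "regulated by multiple stresses"),
) -> tuple[AnnotationTable, MultistressReport]:
    """Assign the multi-stress fallback category.

    A gene receives ``label`` iff it has no existing annotation and its
    expression changed in at least ``min_stresses`` of the evidence
    columns.  Already-annotated genes are never modified, which also
    makes the operation idempotent.
    """
    if min_stresses < 1:
        raise ValueError("min_stresses must be >= 1")
    counts = evidence.n_changed()
    assigned = sorted(
        str(g)
        for g, c in counts.items()
        if c >= min_stresses and str(g) not in table
    )
    new_entries = dict(table.entries)
    for g in assigned:
        new_entries[g] = label
    logger.info("multi-stress rule assigned %d gene(s)", len(assigned))
    return AnnotationTable(new_entries), MultistressReport(len(assigned), tuple(assigned))


def background_counts(table: AnnotationTable, level: int) -> dict[str, int]:
    """Gene count per rollup key at one level; sums to universe_size."""
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level!r}")
    if len(table) == 0:
        raise ValueError("annotation table is empty")
    if level not in table._bg_counts:
        c = Counter(keys[level - 1] for keys in table.expanded_keys.values())
        table._bg_counts[level] = dict(c)
    return dict(table._bg_counts[level])
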