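"""Reading, filtering and writing association edge lists.

The pipeline consumes three two-column delimited text files — lncRNA–disease,
lncRNA–miRNA and miRNA–disease associations — with entity names treated as
opaque strings.  This module deduplicates rows, applies the preprocessing
rules of the study design (drop sparsely annotated lncRNAs, restrict the
lncRNA–miRNA table to entities present in the other two tables), and writes
canonical cleaned edge lists back to disk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .exceptions import ContractError, EdgeListParseError

ENTITY_CLASSES = ("lncRNA", "miRNA", "disease")

Side = Literal["left", "right"]


@dataclass(frozen=True)
class AssociationTable:
    """A deduplicated, typed edge list between two entity classes.

    ``pairs`` preserves first-occurrence order; ``left_names`` /
    ``right_names`` list the distinct entities in order of first appearance.
    """

    left_type: str
    right_type: str
    pairs: tuple[tuple[str, str], ...]
    left_names: tuple[str, ...] = field(init=False)
    right_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.left_type == self.right_type:
            raise ContractError(
                f"left and right entity classes must differ, got {self.left_type!r} twice"
            )
        seen: set[tuple[str, str]] = set()
        lefts: dict[str, None] = {}
        rights: dict[str, None] = {}
        for left, right in self.pairs:
            if not left or not right:
                raise ContractError("entity names must be nonempty after trimming")
            if (left, right) in seen:
                raise ContractError(f"duplicate pair {(left, right)!r}")
            seen.add((left, right))
            lefts.setdefault(left)
            rights.setdefault(right)
        object.__setattr__(self, "left_names", tuple(lefts))
        object.__setattr__(self, "right_names", tuple(rights))

    def __len__(self) -> int:
        return len(self.pairs)

    def degree(self, side: Side) -> dict[str, int]:
        """Pair count per entity on the given side."""
        idx = 0 if side == "left" else 1
        counts: dict[str, int] = {}
        for pair in self.pairs:
            counts[pair[idx]] = counts.get(pair[idx], 0) + 1
        return counts


def make_table(
    left_type: str, right_type: str, pairs: Iterable[tuple[str, str]]
) -> AssociationTable:
    """Build a table from possibly repeated pairs, deduplicating in order."""
    unique: dict[tuple[str, str], None] = {}
    for left, right in pairs:
        unique.setdefault((left.strip(), right.strip()))
    return AssociationTable(left_type, right_type, tuple(unique))


def read_edge_list(
    path: str | Path,
    left_type: str,
    right_type: str,
    delimiter: str = "\t",
    has_header: bool = False,
    tag_column: int | None = None,
    tag_value: str | None = None,
    casefold: bool = False,
) -> AssociationTable:
    """Read a 2-column (optionally tagged) delimited edge list.

    Rows are whitespace-trimmed and deduplicated preserving first occurrence;
    case is preserved unless ``casefold`` lowercases names before matching.
    When ``tag_column``/``tag_value`` are given, only rows whose 0-based
    ``tag_column`` field equals ``tag_value`` are kept (e.g. the "causal"
    annotation of a pre-tagged miRNA–disease file).
    """
    path = Path(path)
    with io.open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 1 if has_header and lines else 0
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise EdgeListParseError(
                f"expected >=2 fields separated by {delimiter!r}, got {len(fields)}",
                line_number=lineno,
            )
        if tag_column is not None:
            if len(fields) <= tag_column:
                raise EdgeListParseError(
                    f"tag column {tag_column} missing", line_number=lineno
                )
            if fields[tag_column].strip() != tag_value:
                continue
        left, right = fields[0].strip(), fields[1].strip()
        if casefold:
            left, right = left.lower(), right.lower()
        if not left or not right:
            raise EdgeListParseError("empty entity name", line_number=lineno)
        pairs.append((left, right))
    return make_table(left_type, right_type, pairs)


def write_edge_list(
    table: AssociationTable, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the table as a sorted delimited file, for reproducible diffs."""
    with io.open(path, "w", encoding="utf-8") as fh:
        for left, right in sorted(table.pairs):
            fh.write(f"{left}{delimiter}{right}\n")


def filter_min_degree(
    table: AssociationTable,
    side: Side = "left",
    min_assoc: int = 2,
    iterate: bool = False,
) -> AssociationTable:
    """Drop entities on one side with fewer than ``min_assoc`` pairs.

    Single-pass by default (degrees checked once against the input table);
    ``iterate`` repeats to a fixed point.  ``min_assoc=2`` reproduces the
    removal of lncRNAs with one or no recorded association.
    """
    if min_assoc < 1:
        raise ContractError(f"min_assoc must be >= 1, got {min_assoc}")
    idx = 0 if side == "left" else 1
    current = table
    while True:
        counts = current.degree(side)
        keep = tuple(p for p in current.pairs if counts[p[idx]] >= min_assoc)
        nxt = AssociationTable(table.left_type, table.right_type, keep)
        if not iterate or len(nxt) == len(current):
            return nxt
        current = nxt


def restrict_to_shared_entities(
    lnc_mir: AssociationTable,
    lnc_dis: AssociationTable,
    mir_dis: AssociationTable,
) -> AssociationTable:
    """Keep lncRNA–miRNA pairs whose lncRNA occurs in the lncRNA–disease data
    and whose miRNA occurs in the miRNA–disease data."""
    if lnc_mir.left_type != lnc_dis.left_type:
        raise ContractError(
            f"lncRNA class mismatch: {lnc_mir.left_type!r} vs {lnc_dis.left_type!r}"
        )
    if lnc_mir.right_type != mir_dis.left_type:
        raise ContractError(
            f"miRNA class mismatch: {lnc_mir.right_type!r} vs {mir_dis.left_type!r}"
        )
    lncs = set(lnc_dis.left_names)
    mirs = set(mir_dis.left_names)
    keep = tuple(p for p in lnc_mir.pairs if p[0] in lncs and p[1] in mirs)
    return AssociationTable(lnc_mir.left_type, lnc_mir.right_type, keep)
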