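"""Reading, writing and validating rating files.

The file dialect is a plain CSV with one row per stakeholder-item pair:
column 1 the stakeholder id, column 2 the item (question) id, then one
column per criterion in roster order (default importance, changeability),
optionally followed by a population column for stratification. Missing
scores are blank cells or the literal ``NA``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ParseError, ValidationError
from .panel import DEFAULT_CRITERIA, RatingPanel

_MISSING_TOKENS = {"", "na", "nan"}


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in _MISSING_TOKENS


def _parse_score(cell: str, row_no: int, col_no: int) -> float:
    if _is_missing(cell):
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise ParseError(
            f"row {row_no}, column {col_no}: non-numeric score {cell.strip()!r}"
        ) from None


@dataclass
class ReplacementEntry:
    """One out-of-range score coerced to missing by :func:`validate_likert`."""

    stakeholder_id: str
    item_id: str
    criterion: str
    original: float


@dataclass
class ValidationLog:
    """Outcome of a Likert-range validation pass."""

    replacements: list[ReplacementEntry] = field(default_factory=list)
    #: (item, criterion) cells left with zero non-missing scores
    empty_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_replacements(self) -> int:
        return len(self.replacements)

    def summary(self) -> str:
        lines = [f"{self.n_replacements} out-of-range score(s) coerced to missing"]
        for r in self.replacements:
            lines.append(
                f"  stakeholder {r.stakeholder_id}, item {r.item_id}, "
                f"{r.criterion}: {r.original:g} -> NA"
            )
        for item, crit in self.empty_cells:
            lines.append(f"  WARNING item {item}, {crit}: no non-missing scores")
        return "\n".join(lines)


def read_ratings(
    path,
    k: int,
    criteria: Sequence[str] = DEFAULT_CRITERIA,
    has_header: Optional[bool] = None,
    population_column: Optional[str] = None,
) -> RatingPanel:
    """Read a rating CSV into a :class:`RatingPanel`.

    Parameters
    ----------
    path:
        CSV file; columns are stakeholder id, item id, then one score column
        per criterion, optionally a population column.
    k:
        Likert scale maximum (>= 2).
    criteria:
        Criterion roster naming the score columns, in file order.
    has_header:
        ``True``/``False`` to force; ``None`` auto-detects (a first row whose
        score cells are non-numeric is taken as a header).
    population_column:
        Name (with a header) or 0-based column index (without) of the column
        holding each item's population label.

    Raises
    ------
    ParseError
        Malformed rows or non-numeric score cells (message names the row).
    ValidationError
        Duplicate (stakeholder, item, criterion) triples.
    """
    path = Path(path)
    criteria = tuple(criteria)
    n_c = len(criteria)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    if not rows:
        raise ParseError(f"{path}: empty file")

    score_slots = range(2, 2 + n_c)
    if has_header is None:
        first = rows[0]
        has_header = len(first) > 2 and any(
            not _is_missing(first[i]) and _score_like(first[i]) is None
            for i in score_slots
            if i < len(first)
        )
    header = rows[0] if has_header else None
    body = rows[1:] if has_header else rows
    if not body:
        raise ParseError(f"{path}: no data rows")

    pop_idx: Optional[int] = None
    if population_column is not None:
        if header is not None and str(population_column) in [h.strip() for h in header]:
            pop_idx = [h.strip() for h in header].index(str(population_column))
        else:
            try:
                pop_idx = int(population_column)
            except (TypeError, ValueError):
                raise ArgumentError(
                    f"population column {population_column!r} not found in header"
                ) from None

    records, strata = [], {}
    for offset, row in enumerate(body):
        row_no = offset + 1 + (1 if has_header else 0)
        if len(row) < 2 + n_c:
            raise ParseError(
                f"row {row_no}: expected at least {2 + n_c} columns, got {len(row)}"
            )
        sid, item = row[0].strip(), row[1].strip()
        if not sid or not item:
            raise ParseError(f"row {row_no}: blank stakeholder or item id")
        for j, crit in enumerate(criteria):
            col = 2 + j
            records.append(
                (sid, item, crit, _parse_score(row[col], row_no, col + 1))
            )
        if pop_idx is not None:
            if pop_idx >= len(row):
                raise ParseError(f"row {row_no}: missing population column")
            label = row[pop_idx].strip()
            if label:
                prev = strata.get(item)
                if prev is not None and prev != label:
                    raise ValidationError(
                        f"row {row_no}: item {item!r} assigned to both "
                        f"{prev!r} and {label!r}"
                    )
                strata[item] = label

    df = pd.DataFrame(records, columns=["stakeholder_id", "item_id", "criterion", "score"])
    return RatingPanel(df, k=k, criteria=criteria, strata=strata or None)


def _score_like(cell: str) -> Optional[float]:
    try:
        return float(cell)
    except ValueError:
        return None


def write_ratings(panel: RatingPanel, path, population_column: str = "population") -> None:
    """Write a panel back to the CSV dialect read by :func:`read_ratings`."""
    wide = panel.data.pivot(index=["stakeholder_id", "item_id"],
                            columns="criterion", values="score")
    wide = wide.reindex(columns=list(panel.criteria)).reset_index()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["id", "item", *panel.criteria]
        if panel.strata is not None:
            header.append(population_column)
        writer.writerow(header)
        for row in wide.itertuples(index=False):
            cells = [row.stakeholder_id, row.item_id]
            for j in range(len(panel.criteria)):
                val = row[2 + j]
                cells.append("" if pd.isna(val) else f"{val:g}")
            if panel.strata is not None:
                cells.append(panel.strata.get(row.item_id, ""))
            writer.writerow(cells)


def validate_likert(panel: RatingPanel) -> tuple[RatingPanel, ValidationLog]:
    """Coerce out-of-range scores to missing, mirroring a range check pass.

    Every score that is not an integer in ``[1, k]`` (zeros, values above k,
    fractional values) is replaced by missing and logged; the record count is
    unchanged, so the operation is idempotent. Items left with zero
    non-missing scores on some criterion are flagged in the log rather than
    dropped.
    """
    df = panel.data.copy()
    scores = df["score"]
    in_range = scores.notna() & (scores >= 1) & (scores <= panel.k) & (scores % 1 == 0)
    bad = scores.notna() & ~in_range

    log = ValidationLog()
    for row in df[bad].itertuples(index=False):
        log.replacements.append(
            ReplacementEntry(row.stakeholder_id, row.item_id, row.criterion, row.score)
        )
    df.loc[bad, "score"] = np.nan

    counts = df.groupby(["item_id", "criterion"], sort=False)["score"].count()
    for (item, crit), n in counts.items():
        if n == 0:
            log.empty_cells.append((item, crit))

    return panel.with_data(df), log
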