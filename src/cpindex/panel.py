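"""Domain containers for stakeholder rating panels.

A panel holds one score per (stakeholder, item, criterion) cell on a k-point
Likert scale, where a cell may be missing (an abstention). Internally the
records live in a long-format :class:`pandas.DataFrame`; missing scores are
``NaN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ValidationError

DEFAULT_CRITERIA = ("importance", "changeability")

#: long-format column order used throughout the package
_COLUMNS = ["stakeholder_id", "item_id", "criterion", "score"]


@dataclass(frozen=True)
class RatingRecord:
    """One stakeholder's score for one item on one criterion.

    ``score`` is ``None`` for an abstention; otherwise an integer in
    ``[1, k]`` once the panel has been validated.
    """

    stakeholder_id: str
    item_id: str
    criterion: str
    score: Optional[float]


@dataclass
class RatingPanel:
    """A full rating panel: records, scale, criterion roster, optional strata.

    Parameters
    ----------
    data:
        Long-format frame with columns ``stakeholder_id``, ``item_id``,
        ``criterion`` (strings) and ``score`` (float, NaN = missing).
    k:
        Likert scale maximum; scores lie in ``[1, k]``.
    criteria:
        Ordered criterion roster (length ``n_c``). The product over this
        roster defines the CPI, so its length sets the upper bound ``k**n_c``.
    strata:
        Optional mapping item_id -> population label for stratified reports.
    """

    data: pd.DataFrame
    k: int
    criteria: Sequence[str] = DEFAULT_CRITERIA
    strata: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 2:
            raise ArgumentError(f"k must be an integer >= 2, got {self.k!r}")
        self.k = int(self.k)
        self.criteria = tuple(str(c) for c in self.criteria)
        if len(self.criteria) < 1:
            raise ArgumentError("criterion roster must not be empty")
        if len(set(self.criteria)) != len(self.criteria):
            raise ArgumentError("criterion roster has duplicates")

        df = self.data.copy()
        missing_cols = [c for c in _COLUMNS if c not in df.columns]
        if missing_cols:
            raise ArgumentError(f"panel data lacks columns {missing_cols}")
        df = df[_COLUMNS].reset_index(drop=True)
        for col in ("stakeholder_id", "item_id", "criterion"):
            df[col] = df[col].astype(str)
        df["score"] = pd.to_numeric(df["score"], errors="raise").astype(float)
        self.data = df

        unknown = set(df["criterion"]) - set(self.criteria)
        if unknown:
            raise ValidationError(f"records use criteria outside the roster: {sorted(unknown)}")
        dup = df.duplicated(subset=["stakeholder_id", "item_id", "criterion"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise ValidationError(
                "duplicate rating for stakeholder "
                f"{first['stakeholder_id']!r}, item {first['item_id']!r}, "
                f"criterion {first['criterion']!r}"
            )
        if self.strata is not None:
            self.strata = {str(k_): str(v) for k_, v in self.strata.items()}

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[RatingRecord],
        k: int,
        criteria: Sequence[str] = DEFAULT_CRITERIA,
        strata: Optional[Mapping[str, str]] = None,
    ) -> "RatingPanel":
        rows = [
            (r.stakeholder_id, r.item_id, r.criterion,
             math.nan if r.score is None else float(r.score))
            for r in records
        ]
        df = pd.DataFrame(rows, columns=_COLUMNS)
        return cls(df, k=k, criteria=criteria, strata=strata)

    # -- accessors --------------------------------------------------------

    @property
    def n_stakeholders(self) -> int:
        return self.data["stakeholder_id"].nunique()

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    @property
    def items(self) -> list[str]:
        """Item ids in order of first appearance."""
        return list(dict.fromkeys(self.data["item_id"]))

    @property
    def records(self) -> list[RatingRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            score = None if pd.isna(row.score) else float(row.score)
            out.append(RatingRecord(row.stakeholder_id, row.item_id, row.criterion, score))
        return out

    def stratum_of(self, item_id: str) -> Optional[str]:
        if self.strata is None:
            return None
        return self.strata.get(str(item_id))

    def item_matrix(self, item_id: str) -> pd.DataFrame:
        """Wide stakeholder-by-criterion score matrix for one item.

        Rows are the stakeholders who have any record for the item (the
        bootstrap resampling units); columns follow the criterion roster;
        missing scores are NaN.
        """
        sub = self.data[self.data["item_id"] == str(item_id)]
        if sub.empty:
            raise ArgumentError(f"unknown item {item_id!r}")
        wide = sub.pivot(index="stakeholder_id", columns="criterion", values="score")
        wide = wide.reindex(columns=list(self.criteria))
        return wide.sort_index()

    def with_data(self, data: pd.DataFrame) -> "RatingPanel":
        """Copy of this panel with replaced records, same k/criteria/strata."""
        return replace(self, data=data)

    def equals(self, other: "RatingPanel") -> bool:
        if self.k != other.k or self.criteria != other.criteria:
            return False
        a = self.data.sort_values(_COLUMNS[:3]).reset_index(drop=True)
        b = other.data.sort_values(_COLUMNS[:3]).reset_index(drop=True)
        return a.equals(b) and (self.strata or {}) == (other.strata or {})
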