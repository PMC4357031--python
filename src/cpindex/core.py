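"""Core CPI arithmetic: criterion means, the product index, bounds,
standardization and priority classification.

The Community Priority Index of an item is the product of its per-criterion
mean ratings,

    CPI_q = prod_c mean_i(x_iqc),

with each mean taken over the stakeholders who actually responded (missing
scores excluded from both sum and denominator). With scores on ``[1, k]``
and ``n_c`` criteria the CPI lies in ``[1, k**n_c]``; min-max scaling by
these theoretical bounds gives the standardized CPI

    sCPI_q = (CPI_q - 1) / (k**n_c - 1)  in  [0, 1],

which is scale-free and comparable across settings. Standardized scores are
classed low / intermediate / high priority by configurable cut-offs
(default below 0.3 / 0.3-0.7 / above 0.7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .errors import ArgumentError, IncompleteItemError, NoResponsesError
from .panel import RatingPanel

DEFAULT_CUTOFFS = (0.3, 0.7)

_EPS = 1e-9


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties away from zero (half-up).

    Operates on the shortest decimal representation of ``x`` so that, e.g.,
    0.295 rounds to 0.30 even though the nearest binary float is fractionally
    below the tie point.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CriterionMean:
    """Per-item, per-criterion mean rating and the respondent count behind it."""

    item_id: str
    criterion: str
    mean: float
    n_respondents: int


@dataclass(frozen=True)
class CPIBounds:
    """Theoretical CPI range: all-ones ratings give 1, all-k give k**n_c."""

    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class CPIResult:
    """Everything computed for one item: observed CPI, CI, standardized
    values, priority class and (once ranked) its within-stratum rank."""

    item_id: str
    population: Optional[str]
    observed_cpi: float
    std_cpi: float
    priority_class: str
    criterion_means: list[CriterionMean] = field(default_factory=list)
    ci: Optional[tuple[float, float]] = None
    std_ci: Optional[tuple[float, float]] = None
    rank: Optional[int] = None


def criterion_mean(panel: RatingPanel, item_id: str, criterion: str) -> CriterionMean:
    """Mean score for one (item, criterion) cell.

    Abstentions are excluded from both numerator and denominator: the sum of
    non-missing scores is divided by the number of respondents for the item,
    not by the panel size.
    """
    item_id, criterion = str(item_id), str(criterion)
    if criterion not in panel.criteria:
        raise ArgumentError(f"criterion {criterion!r} not in roster {panel.criteria}")
    sub = panel.data
    scores = sub.loc[
        (sub["item_id"] == item_id) & (sub["criterion"] == criterion), "score"
    ]
    valid = scores.dropna()
    if valid.empty:
        raise NoResponsesError(item_id, criterion)
    return CriterionMean(item_id, criterion, float(valid.mean()), int(valid.size))


def compute_cpi(means: Sequence[CriterionMean],
                criteria: Optional[Sequence[str]] = None) -> float:
    """Product of criterion means; requires exactly one mean per criterion."""
    seen = [m.criterion for m in means]
    if criteria is not None:
        roster = list(criteria)
        if sorted(seen) != sorted(roster):
            missing = set(roster) - set(seen)
            raise IncompleteItemError(
                f"criterion means {seen} do not cover roster {roster}"
                + (f"; missing {sorted(missing)}" if missing else "")
            )
    elif len(set(seen)) != len(seen) or not seen:
        raise IncompleteItemError(f"duplicate or empty criterion means: {seen}")
    return float(np.prod([m.mean for m in means]))


def item_cpi(panel: RatingPanel, item_id: str) -> tuple[float, list[CriterionMean]]:
    """Observed CPI of one item together with its criterion means."""
    means = [criterion_mean(panel, item_id, c) for c in panel.criteria]
    return compute_cpi(means, panel.criteria), means


def cpi_bounds(k: int, n_c: int) -> CPIBounds:
    """Theoretical CPI bounds ``(1, k**n_c)`` for a k-point scale and n_c criteria."""
    if int(k) != k or k < 2:
        raise ArgumentError(f"k must be an integer >= 2, got {k!r}")
    if int(n_c) != n_c or n_c < 1:
        raise ArgumentError(f"n_c must be a positive integer, got {n_c!r}")
    return CPIBounds(lower=1.0, upper=float(int(k) ** int(n_c)))


def standardize(cpi: float, bounds: CPIBounds) -> float:
    """Map a CPI onto [0, 1] by its theoretical bounds: (cpi - LB)/(UB - LB)."""
    if not (bounds.lower - _EPS <= cpi <= bounds.upper + _EPS):
        raise ArgumentError(
            f"CPI {cpi} outside bounds [{bounds.lower}, {bounds.upper}]"
        )
    return float(np.clip((cpi - bounds.lower) / bounds.width, 0.0, 1.0))


def unstandardize(std_cpi: float, bounds: CPIBounds) -> float:
    """Inverse of :func:`standardize`."""
    if not (-_EPS <= std_cpi <= 1.0 + _EPS):
        raise ArgumentError(f"standardized CPI {std_cpi} outside [0, 1]")
    return float(bounds.lower + std_cpi * bounds.width)


def classify_priority(std_cpi: float,
                      cutoffs: tuple[float, float] = DEFAULT_CUTOFFS) -> str:
    """Priority class of a standardized CPI.

    Below ``low_max`` is low; above ``high_min`` is high; the closed middle
    band (both boundaries included) is intermediate. The defaults 0.3/0.7
    are conventional, not canonical, hence configurable.
    """
    low_max, high_min = cutoffs
    if not (0 < low_max <= high_min < 1):
        raise ArgumentError(f"incoherent cut-offs {cutoffs}")
    if not (0.0 - _EPS <= std_cpi <= 1.0 + _EPS):
        raise ArgumentError(f"standardized CPI {std_cpi} outside [0, 1]")
    if std_cpi < low_max:
        return "low"
    if std_cpi > high_min:
        return "high"
    return "intermediate"
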