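"""Percentile-bootstrap confidence intervals for the CPI.

For each item the resampling unit is a stakeholder's joint row of criterion
scores (preserving within-stakeholder correlation between, e.g., importance
and changeability). Each replicate redraws the item's roster with
replacement at its observed size, recomputes the per-criterion means over
the non-missing resampled scores, and takes their product; the 95% CI is
the 2.5th/97.5th nearest-rank percentile of the replicate CPI distribution.
Replicates in which some criterion ends up with no non-missing value are
discarded and redrawn.

For tiny rosters (n <= 6) the full resampling distribution — all n**n
equally likely ordered redraws — can be enumerated exactly and serves as an
independent oracle for the Monte-Carlo path.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .core import CPIBounds, standardize
from .errors import ArgumentError, DegenerateItemError, NoResponsesError
from .panel import RatingPanel

DEFAULT_REPLICATES = 10_000


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings.

    ``n_replicates`` defaults to 10,000 draws; ``percentiles`` to the
    (2.5, 97.5) pair of a 95% interval. ``joint_rows`` selects the
    resampling unit: stakeholder rows jointly across criteria (default) or
    each criterion independently. ``interpolate`` switches from nearest-rank
    order statistics to linearly interpolated quantiles. ``max_redraws``
    bounds the number of redraw rounds for degenerate replicates.
    """

    n_replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    max_redraws: int = 100
    joint_rows: bool = True
    interpolate: bool = False

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ArgumentError("n_replicates must be >= 1")
        lo, hi = self.percentiles
        if not (0 < lo < hi < 100):
            raise ArgumentError(f"invalid percentile pair {self.percentiles}")


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile CI for one item's CPI, on the raw [1, k**n_c] scale."""

    item_id: str
    lower: float
    upper: float
    n_valid_replicates: int
    n_discarded: int


def _item_rng(seed: int, item_id: str) -> np.random.Generator:
    """Deterministic per-item substream so results do not depend on the
    order in which items are processed."""
    digest = hashlib.sha256(str(item_id).encode("utf-8")).digest()
    item_key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), item_key]))


def nearest_rank(sorted_values: np.ndarray, percentile: float) -> float:
    """Nearest-rank order statistic: the ceil(p/100 * n)-th smallest value."""
    n = len(sorted_values)
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(sorted_values[min(rank, n) - 1])


def _replicate_cpis(matrix: np.ndarray, rng: np.random.Generator,
                    n_draws: int, joint_rows: bool) -> tuple[np.ndarray, np.ndarray]:
    """CPIs of ``n_draws`` bootstrap replicates; second array flags the
    degenerate ones (some criterion with zero non-missing values)."""
    n, n_c = matrix.shape
    if joint_rows:
        idx = rng.integers(0, n, size=(n_draws, n))
        sample = matrix[idx]                              # (B, n, n_c)
    else:
        idx = rng.integers(0, n, size=(n_draws, n, n_c))
        sample = np.take_along_axis(matrix[None, :, :], idx, axis=1)
    counts = np.sum(~np.isnan(sample), axis=1)            # (B, n_c)
    degenerate = (counts == 0).any(axis=1)
    sums = np.nansum(sample, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    cpis = np.prod(means, axis=1)
    return cpis, degenerate


def bootstrap_ci(panel: RatingPanel, item_id: str,
                 config: Optional[BootstrapConfig] = None) -> BootstrapCI:
    """Percentile-bootstrap CI for one item's CPI.

    Raises
    ------
    NoResponsesError
        If some criterion has no observed score for the item.
    DegenerateItemError
        If degenerate replicates persist past ``config.max_redraws`` redraw
        rounds (only possible with heavy missingness).
    """
    config = config or BootstrapConfig()
    matrix = panel.item_matrix(item_id).to_numpy(dtype=float)
    for j, crit in enumerate(panel.criteria):
        if np.isnan(matrix[:, j]).all():
            raise NoResponsesError(item_id, crit)

    rng = _item_rng(config.seed, item_id)
    B = config.n_replicates
    cpis, degenerate = _replicate_cpis(matrix, rng, B, config.joint_rows)
    n_discarded = int(degenerate.sum())
    rounds = 0
    while degenerate.any():
        rounds += 1
        if rounds > config.max_redraws:
            raise DegenerateItemError(
                f"item {item_id!r}: degenerate replicates persisted for "
                f"{config.max_redraws} redraw rounds"
            )
        redraw, still_bad = _replicate_cpis(
            matrix, rng, int(degenerate.sum()), config.joint_rows
        )
        cpis[degenerate] = redraw
        new_flags = np.zeros_like(degenerate)
        new_flags[np.flatnonzero(degenerate)[still_bad]] = True
        n_discarded += int(still_bad.sum())
        degenerate = new_flags

    lo_p, hi_p = config.percentiles
    if config.interpolate:
        lower, upper = np.percentile(cpis, [lo_p, hi_p])
    else:
        cpis.sort()
        lower, upper = nearest_rank(cpis, lo_p), nearest_rank(cpis, hi_p)
    return BootstrapCI(str(item_id), float(lower), float(upper), B, n_discarded)


MAX_EXACT_ROSTER = 6


def exact_resample_distribution(panel: RatingPanel, item_id: str,
                                joint_rows: bool = True) -> dict[float, float]:
    """Exact distribution of the replicate CPI over all ordered resamples.

    Enumerates every one of the ``n**n`` equally likely ordered redraws of an
    item's n-stakeholder roster and computes the CPI of each. Outcomes where
    a criterion has no non-missing value are dropped and the remaining mass
    renormalized, mirroring the Monte-Carlo discard-and-redraw rule. Only
    feasible for n <= 6; an independent oracle for :func:`bootstrap_ci`.
    """
    matrix = panel.item_matrix(item_id).to_numpy(dtype=float)
    n, n_c = matrix.shape
    if n > MAX_EXACT_ROSTER:
        raise ArgumentError(
            f"roster of {n} stakeholders too large to enumerate (max {MAX_EXACT_ROSTER})"
        )
    if not joint_rows:
        # independent per-criterion draws: n**(n*n_c) outcomes; enumerate per
        # criterion and convolve the (independent) mean distributions
        per_crit: list[dict[float, float]] = []
        for j in range(n_c):
            col = matrix[:, j]
            dist: dict[float, float] = {}
            total = 0.0
            for combo in itertools.product(range(n), repeat=n):
                vals = col[list(combo)]
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    continue
                key = float(vals.mean())
                dist[key] = dist.get(key, 0.0) + 1.0
                total += 1.0
            if total == 0:
                raise DegenerateItemError(
                    f"item {item_id!r}: criterion {panel.criteria[j]!r} has no scores"
                )
            per_crit.append({v: p / total for v, p in dist.items()})
        acc = {1.0: 1.0}
        for dist in per_crit:
            nxt: dict[float, float] = {}
            for v1, p1 in acc.items():
                for v2, p2 in dist.items():
                    key = v1 * v2
                    nxt[key] = nxt.get(key, 0.0) + p1 * p2
            acc = nxt
        return acc

    dist: dict[float, float] = {}
    n_valid = 0
    for combo in itertools.product(range(n), repeat=n):
        sample = matrix[list(combo)]
        counts = np.sum(~np.isnan(sample), axis=0)
        if (counts == 0).any():
            continue
        means = np.nansum(sample, axis=0) / counts
        key = float(np.prod(means))
        dist[key] = dist.get(key, 0.0) + 1.0
        n_valid += 1
    if n_valid == 0:
        raise DegenerateItemError(f"item {item_id!r}: every resample is degenerate")
    return {v: c / n_valid for v, c in sorted(dist.items())}


def distribution_percentile(dist: dict[float, float], percentile: float) -> float:
    """Nearest-rank percentile of a discrete value -> probability mapping:
    the smallest value whose cumulative probability reaches p/100."""
    target = percentile / 100.0
    cum = 0.0
    last = None
    for value in sorted(dist):
        cum += dist[value]
        last = value
        if cum >= target - 1e-12:
            return value
    return last  # p ~ 100


def standardize_interval(ci, bounds: CPIBounds) -> tuple[float, float]:
    """Standardize both CI endpoints onto [0, 1]; order is preserved because
    the bounds map is strictly increasing."""
    if isinstance(ci, BootstrapCI):
        lo, hi = ci.lower, ci.upper
    else:
        lo, hi = ci
    return standardize(lo, bounds), standardize(hi, bounds)
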