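"""Synthetic stakeholder rating panels with known truth.

Each item carries one categorical score distribution per criterion over the
levels 1..k, plus an abstention (missing) rate; stakeholders rate
independently. The generator returns the panel together with a truth record
(true criterion means and true CPI per item), so recovery and CI-coverage
checks never re-derive truth from data. A shared-latent mode correlates a
stakeholder's criterion scores within an item, to exercise the joint-row
bootstrap; the default keeps criteria independent, which is sufficient for
testing the aggregation arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import ArgumentError
from .panel import DEFAULT_CRITERIA, RatingPanel


@dataclasses.dataclass(frozen=True)
class ItemScenario:
    """Ground-truth description of one item.

    ``probs`` maps each criterion to a probability vector over the score
    levels 1..k; ``missing_rate`` is the independent per-cell abstention
    probability.
    """

    item_id: str
    probs: Mapping[str, Sequence[float]]
    population: Optional[str] = None
    missing_rate: float = 0.0

    def __post_init__(self):
        if not (0 <= self.missing_rate < 1):
            raise ArgumentError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        for crit, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                raise ArgumentError(
                    f"item {self.item_id!r}, criterion {crit!r}: "
                    "probabilities must be non-negative and sum to 1"
                )

    def true_mean(self, criterion: str) -> float:
        p = np.asarray(self.probs[criterion], dtype=float)
        levels = np.arange(1, len(p) + 1)
        return float(np.dot(levels, p))

    def true_variance(self, criterion: str) -> float:
        p = np.asarray(self.probs[criterion], dtype=float)
        levels = np.arange(1, len(p) + 1)
        m = self.true_mean(criterion)
        return float(np.dot((levels - m) ** 2, p))

    def true_cpi(self, criteria: Sequence[str]) -> float:
        return float(np.prod([self.true_mean(c) for c in criteria]))


@dataclasses.dataclass(frozen=True)
class PanelScenario:
    """A full panel blueprint: stakeholders, scale, roster, items, seed."""

    n_stakeholders: int
    k: int
    items: tuple[ItemScenario, ...]
    criteria: tuple[str, ...] = DEFAULT_CRITERIA
    seed: int = 0
    #: 0 = independent criteria; in (0, 1] = weight of a shared per-(stakeholder,
    #: item) latent uniform driving all criterion draws (rank correlation)
    latent_correlation: float = 0.0

    def __post_init__(self):
        if self.n_stakeholders < 1:
            raise ArgumentError("n_stakeholders must be >= 1")
        if not self.items:
            raise ArgumentError("scenario needs at least one item")
        if not (0 <= self.latent_correlation <= 1):
            raise ArgumentError("latent_correlation must be in [0, 1]")
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        for item in self.items:
            for crit in self.criteria:
                if crit not in item.probs:
                    raise ArgumentError(
                        f"item {item.item_id!r} lacks a distribution for {crit!r}"
                    )
                if len(item.probs[crit]) != self.k:
                    raise ArgumentError(
                        f"item {item.item_id!r}, criterion {crit!r}: "
                        f"probability vector length must equal k={self.k}"
                    )

    # -- JSON round-trip (scenario files for the CLI) ---------------------

    def to_json(self) -> str:
        payload = {
            "n_stakeholders": self.n_stakeholders,
            "k": self.k,
            "criteria": list(self.criteria),
            "seed": self.seed,
            "latent_correlation": self.latent_correlation,
            "items": [
                {
                    "item_id": it.item_id,
                    "population": it.population,
                    "missing_rate": it.missing_rate,
                    "probs": {c: list(map(float, p)) for c, p in it.probs.items()},
                }
                for it in self.items
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PanelScenario":
        d = json.loads(text)
        items = tuple(
            ItemScenario(
                item_id=it["item_id"],
                probs=it["probs"],
                population=it.get("population"),
                missing_rate=it.get("missing_rate", 0.0),
            )
            for it in d["items"]
        )
        return cls(
            n_stakeholders=d["n_stakeholders"], k=d["k"], items=items,
            criteria=tuple(d.get("criteria", DEFAULT_CRITERIA)),
            seed=d.get("seed", 0),
            latent_correlation=d.get("latent_correlation", 0.0),
        )


def generate_panel(scenario: PanelScenario,
                   seed: Optional[int] = None) -> tuple[RatingPanel, dict]:
    """Draw a rating panel from a scenario.

    Returns the panel and a truth record
    ``{item_id: {"means": {criterion: true mean}, "cpi": true CPI,
    "population": label}}``. A fixed seed yields a byte-identical panel.
    A warning (not an error) is emitted when the missing rate is high enough
    that an item plausibly ends up with an empty criterion.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n, k = scenario.n_stakeholders, scenario.k
    stakeholders = [f"S{i + 1}" for i in range(n)]

    rows = []
    truth: dict[str, dict] = {}
    for item in scenario.items:
        if item.missing_rate > 0 and item.missing_rate ** n > 1e-3:
            warnings.warn(
                f"item {item.item_id!r}: missing_rate {item.missing_rate} with "
                f"{n} stakeholders leaves a criterion empty with probability "
                f"{item.missing_rate ** n:.2%}",
                stacklevel=2,
            )
        latent = rng.standard_normal(size=n)
        for crit in scenario.criteria:
            p = np.asarray(item.probs[crit], dtype=float)
            cdf = np.cumsum(p)
            if scenario.latent_correlation > 0:
                # Gaussian copula: marginals stay exactly the requested
                # categorical distributions at any correlation weight
                w = scenario.latent_correlation
                z = math.sqrt(w) * latent + math.sqrt(1 - w) * rng.standard_normal(size=n)
                u = ndtr(z)
            else:
                u = rng.uniform(size=n)
            scores = (np.searchsorted(cdf, u, side="right") + 1).astype(float)
            np.clip(scores, 1, k, out=scores)
            if item.missing_rate > 0:
                mask = rng.uniform(size=n) < item.missing_rate
                scores[mask] = np.nan
            for sid, s in zip(stakeholders, scores):
                rows.append((sid, item.item_id, crit, s))
        truth[item.item_id] = {
            "means": {c: item.true_mean(c) for c in scenario.criteria},
            "cpi": item.true_cpi(scenario.criteria),
            "population": item.population,
        }

    df = pd.DataFrame(rows, columns=["stakeholder_id", "item_id", "criterion", "score"])
    strata = {it.item_id: it.population for it in scenario.items
              if it.population is not None}
    panel = RatingPanel(df, k=k, criteria=scenario.criteria, strata=strata or None)
    return panel, truth


def consensus_scenario_pair(base: ItemScenario,
                            spread_delta: float) -> tuple[ItemScenario, ItemScenario]:
    """A (low-dispersion, high-dispersion) scenario pair with identical means.

    The high-dispersion member mixes the base distribution with weight
    ``spread_delta`` of the maximum-variance two-point distribution on
    {1, k} that shares each criterion's mean, so means match exactly while
    variance increases. Infeasible (error) when no extra dispersion exists:
    a boundary mean (1 or k) or a base already at maximal variance.
    """
    if not (0 <= spread_delta <= 1):
        raise ArgumentError(f"spread_delta must be in [0, 1], got {spread_delta}")
    if spread_delta == 0:
        return base, base

    new_probs = {}
    widened_any = False
    for crit, p in base.probs.items():
        p = np.asarray(p, dtype=float)
        k = len(p)
        m = base.true_mean(crit)
        if math.isclose(m, 1.0) or math.isclose(m, float(k)):
            raise ArgumentError(
                f"criterion {crit!r}: mean {m} is at the scale boundary; "
                "no dispersion increase is possible"
            )
        extreme = np.zeros(k)
        extreme[0] = (k - m) / (k - 1)
        extreme[-1] = (m - 1) / (k - 1)
        mixed = (1 - spread_delta) * p + spread_delta * extreme
        if not np.allclose(mixed, p):
            widened_any = True
        new_probs[crit] = mixed
    if not widened_any:
        raise ArgumentError(
            "base distributions already have maximal variance for their means"
        )
    high = dataclasses.replace(base, probs=new_probs)
    return base, high


def default_scenario(n_stakeholders: int = 6, seed: int = 0) -> PanelScenario:
    """A three-population demonstration scenario (9 + 7 + 5 items) with
    priorities spanning the low/intermediate/high bands, on the default
    3-point scale with two criteria and a small panel of six raters —
    the shape a small community needs-assessment exercise takes."""
    def probs_for(mean_level: float) -> list[float]:
        # two-point distribution on adjacent levels achieving the target mean
        lo = min(2, max(1, int(mean_level)))
        w = mean_level - lo
        p = [0.0, 0.0, 0.0]
        p[lo - 1] = 1 - w
        p[lo] = w
        return p

    items = []
    specs = {"A": 9, "B": 7, "C": 5}
    target_means = np.linspace(2.9, 1.6, num=max(specs.values()))
    for pop, count in specs.items():
        for i in range(count):
            m = float(target_means[i])
            items.append(
                ItemScenario(
                    item_id=f"{pop}{i + 1}",
                    population=pop,
                    probs={"importance": probs_for(m),
                           "changeability": probs_for(max(1.0, m - 0.2))},
                    missing_rate=0.05,
                )
            )
    return PanelScenario(n_stakeholders=n_stakeholders, k=3,
                         items=tuple(items), seed=seed)
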