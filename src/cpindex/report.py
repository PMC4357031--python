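"""Population-stratified, descending-ranked priority reports.

The report mirrors the tabular shape practitioners use for priority
setting: one block per target population, items sorted by standardized CPI
(highest priority first), with observed CPI, bootstrap CI, standardized
values, priority class and rank. A merged, globally ranked view across
populations is available for cross-population comparison; the per-stratum
view remains primary.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional

from . import core
from .bootstrap import BootstrapConfig, bootstrap_ci, standardize_interval
from .core import (CPIResult, classify_priority, cpi_bounds, item_cpi,
                   round_half_up, standardize)
from .errors import ArgumentError, ComputationError
from .panel import RatingPanel

#: stratum label used for items without a population assignment
DEFAULT_STRATUM = "all"

CSV_COLUMNS = [
    "population", "issue", "observed_cpi", "ci_lower", "ci_upper",
    "std_cpi", "std_ci_lower", "std_ci_upper", "priority_class", "rank",
]


@dataclasses.dataclass
class PriorityReport:
    """Ranked CPI results grouped by population stratum.

    ``strata`` is an ordered list of (population label, ranked results);
    within each stratum results are sorted by standardized CPI descending,
    ties broken by item id ascending, and carry ranks 1..m. ``skipped``
    lists items that could not be computed, with reasons.
    """

    strata: list[tuple[str, list[CPIResult]]]
    metadata: dict
    skipped: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    @property
    def results(self) -> list[CPIResult]:
        return [r for _, results in self.strata for r in results]

    def merged(self) -> list[CPIResult]:
        """Globally ranked view across all strata (ranks reassigned)."""
        merged = sorted(self.results, key=lambda r: (-r.std_cpi, r.item_id))
        out = []
        for i, r in enumerate(merged, start=1):
            out.append(dataclasses.replace(r, rank=i))
        return out


def build_report(
    panel: RatingPanel,
    config: Optional[BootstrapConfig] = None,
    cutoffs: tuple[float, float] = core.DEFAULT_CUTOFFS,
    classify_full_precision: bool = False,
    validation_summary: Optional[str] = None,
) -> PriorityReport:
    """Compute CPI, CI, standardized values, class and rank for every item.

    Pass ``config=None`` to skip the bootstrap (point estimates only).
    Classification applies the cut-offs to the 2-decimal reported value by
    default so that the printed table is self-consistent; set
    ``classify_full_precision`` to classify on the unrounded value instead.
    Items that cannot be computed (no responses on some criterion) are
    recorded in ``skipped``, not raised.
    """
    if panel.data.empty:
        raise ArgumentError("empty panel: nothing to report")
    bounds = cpi_bounds(panel.k, panel.n_criteria)

    by_stratum: dict[str, list[CPIResult]] = {}
    skipped: list[tuple[str, str]] = []
    for item in panel.items:
        try:
            cpi, means = item_cpi(panel, item)
        except ComputationError as err:
            skipped.append((item, str(err)))
            continue
        std = standardize(cpi, bounds)
        ci = std_ci = None
        if config is not None and config.n_replicates > 0:
            boot = bootstrap_ci(panel, item, config)
            ci = (boot.lower, boot.upper)
            std_ci = standardize_interval(boot, bounds)
        class_input = std if classify_full_precision else round_half_up(std, 2)
        result = CPIResult(
            item_id=item,
            population=panel.stratum_of(item),
            observed_cpi=cpi,
            std_cpi=std,
            priority_class=classify_priority(class_input, cutoffs),
            criterion_means=means,
            ci=ci,
            std_ci=std_ci,
        )
        label = result.population if result.population is not None else DEFAULT_STRATUM
        by_stratum.setdefault(label, []).append(result)

    strata = []
    for label in sorted(by_stratum):
        results = sorted(by_stratum[label], key=lambda r: (-r.std_cpi, r.item_id))
        for i, r in enumerate(results, start=1):
            r.rank = i
        strata.append((label, results))

    metadata = {
        "k": panel.k,
        "n_criteria": panel.n_criteria,
        "criteria": list(panel.criteria),
        "n_stakeholders": panel.n_stakeholders,
        "bounds": {"lower": bounds.lower, "upper": bounds.upper},
        "cutoffs": list(cutoffs),
        "classify_full_precision": classify_full_precision,
        "bootstrap": None if config is None else {
            "n_replicates": config.n_replicates,
            "seed": config.seed,
            "percentiles": list(config.percentiles),
            "joint_rows": config.joint_rows,
            "interpolate": config.interpolate,
        },
        "validation": validation_summary,
    }
    return PriorityReport(strata=strata, metadata=metadata, skipped=skipped)


def _fmt2(value: Optional[float]) -> str:
    return "" if value is None else f"{round_half_up(value, 2):.2f}"


def _rows(report: PriorityReport) -> list[list[str]]:
    rows = []
    for population, results in report.strata:
        for r in results:
            ci_lo, ci_hi = r.ci if r.ci else (None, None)
            sci_lo, sci_hi = r.std_ci if r.std_ci else (None, None)
            rows.append([
                population, r.item_id, _fmt2(r.observed_cpi), _fmt2(ci_lo),
                _fmt2(ci_hi), _fmt2(r.std_cpi), _fmt2(sci_lo), _fmt2(sci_hi),
                r.priority_class, str(r.rank),
            ])
    return rows


def report_to_dict(report: PriorityReport, include_merged: bool = False) -> dict:
    """Lossless dict form (full precision) for JSON serialization."""
    def result_dict(r: CPIResult) -> dict:
        return {
            "item_id": r.item_id,
            "population": r.population,
            "observed_cpi": r.observed_cpi,
            "std_cpi": r.std_cpi,
            "ci": list(r.ci) if r.ci else None,
            "std_ci": list(r.std_ci) if r.std_ci else None,
            "priority_class": r.priority_class,
            "rank": r.rank,
            "criterion_means": [
                {"criterion": m.criterion, "mean": m.mean,
                 "n_respondents": m.n_respondents}
                for m in r.criterion_means
            ],
        }

    payload = {
        "metadata": report.metadata,
        "strata": [
            {"population": label, "results": [result_dict(r) for r in results]}
            for label, results in report.strata
        ],
        "skipped": [{"item_id": i, "reason": why} for i, why in report.skipped],
    }
    if include_merged:
        payload["merged"] = [result_dict(r) for r in report.merged()]
    return payload


def report_from_dict(payload: dict) -> PriorityReport:
    """Rebuild a :class:`PriorityReport` from :func:`report_to_dict` output."""
    def result(d: dict) -> CPIResult:
        return CPIResult(
            item_id=d["item_id"],
            population=d["population"],
            observed_cpi=d["observed_cpi"],
            std_cpi=d["std_cpi"],
            priority_class=d["priority_class"],
            criterion_means=[
                core.CriterionMean(d["item_id"], m["criterion"], m["mean"],
                                   m["n_respondents"])
                for m in d.get("criterion_means", [])
            ],
            ci=tuple(d["ci"]) if d.get("ci") else None,
            std_ci=tuple(d["std_ci"]) if d.get("std_ci") else None,
            rank=d.get("rank"),
        )

    return PriorityReport(
        strata=[(s["population"], [result(r) for r in s["results"]])
                for s in payload["strata"]],
        metadata=payload["metadata"],
        skipped=[(s["item_id"], s["reason"]) for s in payload.get("skipped", [])],
    )


def write_report(report: PriorityReport, path, format: str = "csv",
                 include_merged: bool = False) -> None:
    """Write a report as ``csv`` (2-decimal rendering), ``json`` (full
    precision, lossless round-trip) or ``table`` (aligned plain text)."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            writer.writerows(_rows(report))
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report_to_dict(report, include_merged=include_merged),
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "table":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(format_table(report, include_merged=include_merged))
    else:
        raise ArgumentError(f"unknown report format {format!r}")


def format_table(report: PriorityReport, include_merged: bool = False) -> str:
    """Aligned plain-text rendering of the report."""
    rows = [CSV_COLUMNS] + _rows(report)
    if include_merged:
        merged = PriorityReport(strata=[("(merged)", report.merged())],
                                metadata=report.metadata)
        rows += _rows(merged)
    widths = [max(len(row[i]) for row in rows) for i in range(len(CSV_COLUMNS))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
             for row in rows]
    lines.insert(1, "  ".join("-" * w for w in widths))
    return "\n".join(lines) + "\n"
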