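import math

import pytest
from hypothesis import HealthCheck, settings

import cpindex as cp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_panel(item_scores, k=3, criteria=("importance", "changeability"),
               strata=None):
    """Build a panel from {item: [(imp, chg, ...), ...]} with one tuple per
    stakeholder; None entries are missing scores."""
    records = []
    for item, rows in item_scores.items():
        for i, scores in enumerate(rows):
            for crit, s in zip(criteria, scores):
                records.append(cp.RatingRecord(f"S{i + 1}", item, crit, s))
    return cp.RatingPanel.from_records(records, k=k, criteria=criteria,
                                       strata=strata)


def brute_force_cpi(panel, item_id):
    """Independent evaluation of the criterion-mean product, by plain loops
    over the record list (no pandas, no shared code path)."""
    sums = {c: 0.0 for c in panel.criteria}
    counts = {c: 0 for c in panel.criteria}
    for rec in panel.records:
        if rec.item_id == item_id and rec.score is not None:
            sums[rec.criterion] += rec.score
            counts[rec.criterion] += 1
    product = 1.0
    for c in panel.criteria:
        assert counts[c] > 0
        product *= sums[c] / counts[c]
    return product


@pytest.fixture
def tiny_panel():
    """Two stakeholders, one item, one abstention on changeability."""
    return make_panel({"Q1": [(3, 2), (2, None)]})


@pytest.fixture
def two_rater_extremes():
    """Two stakeholders at opposite scale ends: resample CPIs {1, 4, 4, 9}."""
    return make_panel({"Q": [(1, 1), (3, 3)]})
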