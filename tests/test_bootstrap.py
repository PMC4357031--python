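import math

import numpy as np
import pytest

import cpindex as cp

from conftest import make_panel

B39 = cp.cpi_bounds(3, 2)


def config(**kw):
    kw.setdefault("n_replicates", 2000)
    kw.setdefault("seed", 11)
    return cp.BootstrapConfig(**kw)


class TestBootstrapCI:
    def test_constant_ratings_give_point_interval(self):
        panel = make_panel({"Q": [(3, 3)] * 5})
        ci = cp.bootstrap_ci(panel, "Q", config())
        assert (ci.lower, ci.upper) == (9.0, 9.0)
        assert ci.n_discarded == 0

    def test_single_stakeholder_resamples_to_itself(self):
        panel = make_panel({"Q": [(2, 3)]})
        ci = cp.bootstrap_ci(panel, "Q", config())
        assert (ci.lower, ci.upper) == (6.0, 6.0)

    def test_two_extreme_raters_span_full_range(self, two_rater_extremes):
        # resample CPIs are {1, 4, 4, 9}; both 2.5%/97.5% nearest ranks land
        # in the outer quarter-mass atoms
        ci = cp.bootstrap_ci(two_rater_extremes, "Q", config(n_replicates=10000))
        assert (ci.lower, ci.upper) == (1.0, 9.0)

    def test_fixed_seed_reproducible(self, tiny_panel):
        a = cp.bootstrap_ci(tiny_panel, "Q1", config())
        b = cp.bootstrap_ci(tiny_panel, "Q1", config())
        assert (a.lower, a.upper, a.n_discarded) == (b.lower, b.upper, b.n_discarded)

    def test_result_independent_of_item_processing_order(self):
        one = make_panel({"Q1": [(3, 2), (2, 1), (1, 3)],
                          "Q2": [(2, 2), (3, 3), (1, 1)]})
        other = make_panel({"Q2": [(2, 2), (3, 3), (1, 1)],
                            "Q1": [(3, 2), (2, 1), (1, 3)]})
        for item in ("Q1", "Q2"):
            a = cp.bootstrap_ci(one, item, config())
            b = cp.bootstrap_ci(other, item, config())
            assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_missing_rows_discarded_and_redrawn(self, tiny_panel):
        # changeability is observed for only one of two stakeholders, so a
        # quarter of joint resamples are degenerate and must be redrawn
        ci = cp.bootstrap_ci(tiny_panel, "Q1", config(n_replicates=4000))
        assert ci.n_discarded > 0
        assert ci.n_valid_replicates == 4000
        assert 1.0 <= ci.lower <= ci.upper <= 9.0

    def test_all_missing_criterion_raises(self):
        panel = make_panel({"Q": [(2, None), (3, None)]})
        with pytest.raises(cp.NoResponsesError, match="changeability"):
            cp.bootstrap_ci(panel, "Q", config())

    def test_redraw_guard_trips(self, tiny_panel):
        with pytest.raises(cp.DegenerateItemError):
            cp.bootstrap_ci(tiny_panel, "Q1",
                            config(n_replicates=4000, max_redraws=0))

    def test_interpolated_quantiles_option(self, two_rater_extremes):
        ci = cp.bootstrap_ci(two_rater_extremes, "Q",
                             config(n_replicates=10000, interpolate=True))
        # linear interpolation pulls the endpoints off the outer atoms
        assert ci.lower >= 1.0 and ci.upper <= 9.0

    def test_ci_within_bounds_on_random_panels(self):
        rng = np.random.default_rng(5)
        for trial in range(50):
            rows = [
                tuple(int(rng.integers(1, 4)) if rng.uniform() > 0.2 else None
                      for _ in range(2))
                for _ in range(int(rng.integers(2, 7)))
            ]
            panel = make_panel({"Q": rows})
            try:
                ci = cp.bootstrap_ci(panel, "Q", config(n_replicates=300, seed=trial))
            except cp.NoResponsesError:
                continue
            assert 1.0 <= ci.lower <= ci.upper <= 9.0


class TestNearestRank:
    def test_order_statistic_convention(self):
        values = np.arange(1.0, 101.0)  # 1..100
        assert cp.nearest_rank(values, 2.5) == 3.0   # ceil(2.5) = 3rd smallest
        assert cp.nearest_rank(values, 97.5) == 98.0
        assert cp.nearest_rank(values, 100.0) == 100.0
        assert cp.nearest_rank(values, 0.1) == 1.0


class TestExactDistribution:
    def test_single_row_point_mass(self):
        panel = make_panel({"Q": [(2, 3)]})
        assert cp.exact_resample_distribution(panel, "Q") == {6.0: 1.0}

    def test_two_distinct_rows_four_outcomes(self, two_rater_extremes):
        dist = cp.exact_resample_distribution(two_rater_extremes, "Q")
        assert dist == {1.0: 0.25, 4.0: 0.5, 9.0: 0.25}
        assert cp.distribution_percentile(dist, 2.5) == 1.0
        assert cp.distribution_percentile(dist, 97.5) == 9.0

    def test_three_rows_mass_conservation(self):
        panel = make_panel({"Q": [(1, 2), (2, 3), (3, 1)]})
        dist = cp.exact_resample_distribution(panel, "Q")
        assert sum(dist.values()) == pytest.approx(1.0)
        assert all(1.0 <= v <= 9.0 for v in dist)

    def test_large_roster_refused(self):
        panel = make_panel({"Q": [(2, 2)] * 7})
        with pytest.raises(cp.ArgumentError, match="too large"):
            cp.exact_resample_distribution(panel, "Q")

    def test_monte_carlo_converges_to_enumeration(self):
        """MC percentile endpoints approach the exact nearest-rank values."""
        panel = make_panel({"Q": [(1, 2), (2, 3), (3, 1), (3, 3)]})
        dist = cp.exact_resample_distribution(panel, "Q")
        lo_exact = cp.distribution_percentile(dist, 2.5)
        hi_exact = cp.distribution_percentile(dist, 97.5)
        ci = cp.bootstrap_ci(panel, "Q", config(n_replicates=50000, seed=2))
        # endpoints land on atoms of the exact distribution, at or adjacent
        # to the exact percentile
        atoms = sorted(dist)
        assert ci.lower in atoms and ci.upper in atoms
        assert abs(atoms.index(ci.lower) - atoms.index(lo_exact)) <= 1
        assert abs(atoms.index(ci.upper) - atoms.index(hi_exact)) <= 1

    def test_independent_resampling_matches_convolved_enumeration(self):
        panel = make_panel({"Q": [(1, 3), (3, 1), (2, 2)]})
        dist = cp.exact_resample_distribution(panel, "Q", joint_rows=False)
        assert sum(dist.values()) == pytest.approx(1.0)
        ci = cp.bootstrap_ci(panel, "Q",
                             config(n_replicates=50000, seed=4, joint_rows=False))
        atoms = sorted(dist)
        lo_exact = cp.distribution_percentile(dist, 2.5)
        hi_exact = cp.distribution_percentile(dist, 97.5)
        assert ci.lower in atoms and ci.upper in atoms
        assert abs(atoms.index(ci.lower) - atoms.index(lo_exact)) <= 1
        assert abs(atoms.index(ci.upper) - atoms.index(hi_exact)) <= 1


class TestStandardizeInterval:
    @pytest.mark.parametrize("raw,expected", [
        ((6.60, 9.00), (0.70, 1.00)),
        ((1.80, 5.28), (0.10, 0.54)),
        ((9.0, 9.0), (1.0, 1.0)),
    ])
    def test_reference_endpoints(self, raw, expected):
        lo, hi = cp.standardize_interval(raw, B39)
        assert (cp.round_half_up(lo), cp.round_half_up(hi)) == expected

    def test_accepts_bootstrap_ci_object(self, two_rater_extremes):
        ci = cp.bootstrap_ci(two_rater_extremes, "Q", config(n_replicates=10000))
        assert cp.standardize_interval(ci, B39) == (0.0, 1.0)

    def test_out_of_bounds_endpoint_rejected(self):
        with pytest.raises(cp.ArgumentError):
            cp.standardize_interval((0.5, 8.0), B39)
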