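# Methods

## Model and assumptions

The Community Priority Index treats a prioritization exercise as a panel of
`n_I` stakeholders scoring `N_q` issues against `n_c` decision criteria on
a k-point Likert scale, `1 ≤ x_iqc ≤ k`. Three modelling commitments follow
from that framing:

1. **Respondent-count means.** Abstentions are expected and legitimate
   (forced responses would be coercive), so each (item, criterion) mean
   divides by the number of respondents for that cell, never by the panel
   size. A cell with zero respondents is an error (or a skipped, logged item
   at the report level), never a silent zero.
2. **Product aggregation.** `CPI_q = Π_c x̄*_qc` deliberately rewards items
   that score well on *all* criteria; a highly important but unchangeable
   issue is pulled down multiplicatively, not averaged up. All criteria are
   treated symmetrically (no weights).
3. **Bounds-based standardization.** Setting every score to 1 (resp. k)
   gives the theoretical range `[1, k^n_c]`, so
   `sCPI = (CPI − 1)/(k^n_c − 1)` is a deterministic, strictly increasing
   map onto [0, 1]. Rankings are therefore identical on the raw and
   standardized scales; standardization only buys cross-scale
   comparability.

The Likert domain is `[1, k]` throughout. Scores of 0 — which appear in
some field instruments — are outside the domain and are coerced to missing
by `validate_likert`, consistently with the bounds derivation (a 0 would
make the lower bound 0, not 1, and break the standardization above).

## Bootstrap confidence intervals

With small panels (often fewer than 30 stakeholders, sometimes 6) normal
asymptotics are untrustworthy, so the 95% CI is a percentile bootstrap:

- **Resampling unit**: a stakeholder's joint row of criterion scores for
  the item, drawn with replacement at the observed roster size. Joint rows
  preserve within-stakeholder correlation between criteria (a rater who
  finds an issue important *and* changeable stays that way in every
  replicate). A flag switches to independent per-criterion resampling for
  sensitivity analysis.
- **Missingness at the replicate level**: missing scores travel with their
  rows; replicate means use the non-missing values only, mirroring the
  observed-data rule. A replicate in which some criterion has no
  non-missing value is discarded and redrawn (counted; a guard of 100
  consecutive fruitless redraw rounds raises instead of looping).
- **Replicates**: B = 10,000 by default, configurable.
- **Percentile convention**: nearest-rank order statistics — ranks
  ⌈0.025·B⌉ and ⌈0.975·B⌉ of the sorted replicate CPIs. Nearest-rank keeps
  every endpoint an actually realized CPI value, which is what the
  enumeration oracle (below) predicts; linearly interpolated quantiles are
  available by option.
- **Reproducibility**: one seed per run; each item gets a substream derived
  from (seed, SHA-256 of the item id), so results are bit-reproducible and
  independent of item processing order.

CI width is read as (inverse) consensus: a wide interval means opinions
diverge. The suite checks the corresponding monotonicity — mean-preserving
increases in rating dispersion do not shrink the expected width.

### Enumeration oracle

For rosters of n ≤ 6 stakeholders, `exact_resample_distribution` enumerates
all `n^n` equally likely ordered resamples and returns the exact replicate-
CPI distribution (degenerate outcomes dropped and mass renormalized, the
exact-analysis analogue of discard-and-redraw). Monte-Carlo endpoints are
tested against this oracle: at B = 100,000 each endpoint must be an atom of
the exact distribution whose cumulative-probability interval contains the
target mass within 4·√(p(1−p)/B) Monte-Carlo error, and in point-mass cases
(where the nearest-rank target falls deep inside a fat atom) the match is
exact.

## Classification, rounding, reporting

- Reported numbers are rounded **half-up** to 2 decimals, applied to the
  shortest decimal representation of the value so that, e.g., 0.295 renders
  as 0.30; internal arithmetic keeps full precision (JSON reports are
  lossless).
- Cut-offs 0.3/0.7 put exactly-0.3 and exactly-0.7 in the closed
  intermediate band; the cut-offs are conventional and configurable.
- Classification applies the cut-offs to the *rounded* value by default, so
  a printed 0.70 is never classed "high" — the table stays self-consistent.
  A flag classifies on full precision instead.
- Reports are stratified by population; within a stratum items sort by
  standardized CPI descending with ties broken by item id ascending, and
  carry ranks 1..m. Items without a label form a default `all` stratum. A
  merged, globally re-ranked view is available for cross-population
  comparison; the per-stratum view is primary.

## Synthetic data generator

`cpindex.synthetic` generates panels with controlled truth: each item has a
categorical score distribution per criterion over levels 1..k, an
independent per-cell abstention probability, and an optional Gaussian-
copula latent correlation that couples a stakeholder's criterion scores
within an item (the copula keeps the categorical marginals — hence the true
means and true CPI — exact at any correlation weight). Truth records (true
means, true CPI) are emitted alongside the panel so recovery and coverage
tests never re-derive truth from data.

What it emulates: small rating panels, abstention, varying consensus,
unbalanced per-population item lists (the built-in demonstration scenario
uses three populations with 9/7/5 items, six raters, a 3-point scale and a
5% abstention rate — the shape of a small community needs assessment).
What it does not: panel sociology (herding, dominance, strategic voting),
item-order effects, non-stationary raters. Passing tests therefore certify
the aggregation, resampling and reporting machinery, not the behavioural
realism of any particular stakeholder process.

`consensus_scenario_pair` builds matched low/high-dispersion scenarios by
mixing a base distribution with the maximum-variance two-point distribution
on {1, k} sharing each criterion's mean — means match exactly, variance
rises. It refuses boundary means and already-maximal-variance bases, where
no mean-preserving spread exists.

## Test problem sizes and numerical choices

The always-on suite uses problem sizes chosen to make each property
decisive while keeping the whole run fast: oracle equivalence at
B = 100,000 on panels of n ≤ 4; CI-bounds checks over 1,000 random panels
at B = 200; coverage of the true CPI over 500 synthetic repetitions at
n = 30 stakeholders and B = 2,000 (expected coverage accepted in
[0.90, 0.99] — the percentile bootstrap is approximate at small n, and
the discreteness of Likert data makes exact 95% unattainable); width
monotonicity over 100 paired repetitions at n = 6, B = 300.

Degenerate inputs: single-stakeholder items yield zero-width CIs (the row
resamples to itself); constant ratings yield point-mass distributions;
items emptied by validation are flagged and skipped with a logged reason,
not fatal. Bounds checks in `standardize` use a 1e-9 tolerance to absorb
float round-off at the interval edges.

## Known limitations

- The percentile bootstrap under-covers slightly for very small or very
  skewed panels; BCa/studentized variants are out of scope.
- One row of the reference priority table frozen into the acceptance tests
  (issue C1) carries a standardized CI lower endpoint (0.69) inconsistent
  with its own raw endpoint (6.67 → 0.71); the tests reproduce every
  internally consistent cell and document that exception in place.
- Criteria are unweighted; weighted products or additive composites are
  deliberate non-goals, as are survey design and consensus-building
  procedure support (the index quantifies ratings however they were
  elicited).
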