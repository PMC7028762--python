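# Methods

## Study design being modelled

A single-arm pre-post economic evaluation from the payer perspective.
Service utilization is surveyed retrospectively at four visits: the 6
months before first contact (`pre6m`) and three follow-up intervals
covering the 12 study months (baseline→3 m, 3→6 m, 6→12 m; `fu1..fu3`).
Quality of life (SF-12) is measured at each visit. Effects are QALYs,
costs are EUR expenditures; the comparison is the client's own prior year.

## Costing

Expenditure = units × unit cost per service item; items without a
meaningful unit price (medication, miscellaneous complementary services,
other contacts) carry direct EUR amounts. The unit-cost table is
configuration data (CSV preset with twelve German 2015 items); no attempt
is made to re-derive prices from remuneration catalogues.

*Annualization.* All pre-period quantities are doubled to a 12-month
window. *Counseling fee.* A flat 100 €/client is added once to the post
window (after imputation, so it is never carried forward).

*Cost LOCF.* A follow-up interval after a client's last observed visit
receives the per-item costs of the last complete follow-up interval,
scaled by the ratio of interval lengths — carrying a 3-month interval
into the final 6-month interval doubles it. Unscaled carry-forward would
systematically undercount the final interval; the scaling is a package
design choice and is flagged per row (`locf`). A client with no complete
follow-up at all falls back to carrying the pre-period *rates* forward
(flag `pre_rate`); excluding such clients instead would change the
denominator, which the reporting layout fixes at the full cohort.

*Aggregation.* Per category and 12-month window: user count (clients with
positive cost), per-user mean (total / users), per-client mean
(total / n, non-users as zero), total, and post-minus-pre difference.
The overall total is defined as the sum of the item totals, so
conservation holds exactly before any display rounding. 95% CIs are
normal-approximation mean ± 1.96·SE; the symmetric form matches the
reporting convention of such studies (lower bounds may be negative), and
the per-user CI is suppressed for a single user. On real data these CIs
cannot be validated here (no individual-level data exist); they are
validated on synthetic cohorts only.

## Quality of life and utilities

SF-12 responses are scored with the published US 1998 norm-based
regression weights (constants 56.57706 / 60.75781), loaded from a
versioned, checksummed CSV; the German-adaptation weights can be swapped
in by pointing at another file of the same layout. A visit with any
missing item yields no score (complete-case per visit) and is handled by
LOCF downstream.

The SF-6D classification maps seven SF-12 items onto six dimensions
(physical functioning, role limitation, social functioning, pain, mental
health, vitality). Role limitation combines the physical and emotional
role items (none / physical only / emotional only / both). The 6-category
frequency items collapse "a good bit of the time" with "some of the
time"; the collapse is monotone by construction and is a package design
choice, as is the dimension–item assignment, since the published mapping
is not distributed with this package.

The shipped tariff is a **synthetic stand-in** (see the file header):
it has the exact structural form of the published UK valuation model —
utility = 1 − Σ level decrements − one MOST penalty when any dimension is
at its most severe level, decrements monotone within dimension, best
state = 1, floor 0.380 — but its decrement values are not the published
estimates. All utility-dependent calibration targets are therefore
defined *through* the pipeline under this tariff, and any tariff file
with the same layout can be substituted. Dominance (a level-wise
no-worse state never has lower utility) holds for any non-negative
monotone decrement file and is property-tested.

QoL LOCF replaces missing visit utilities with the most recent observed
value; a missing baseline is an error (the analysis cohort requires a
baseline interview).

## QALYs

Post-period QALY: trapezoid rule over the LOCF-completed trajectory at
nominal visit times 0, 0.25, 0.5, 1 years (actual interview dates are
supported via `visit_times` but nominal is the default — the generator
produces no interview-date jitter). Pre-period QALY: baseline utility
assumed stable over the prior year, so Q_pre = u(0) × 1 yr. QALYs are
computed per client and then averaged; with shared visit times this
coincides with the AUC of the mean trajectory (tested). No discounting
and no half-cycle correction over the 12-month horizon.

Note an arithmetic fact about the published trajectory: the trapezoid of
the printed mean utilities (0.6051, 0.6535, 0.6602, 0.6927) is 0.6598,
not the printed post-period QALY of 0.6618; the gap is consistent with
per-client interview dates or unrounded utilities, which are not
recoverable. The package therefore validates the AUC against the
hand-computed trapezoid and exact identities (Δ = 0.6618 − 0.6050 =
0.0568), not against the unreproducible 0.6618 itself.

## Cost-effectiveness

Per-client paired deltas (post − pre) for cost and QALYs. Quadrants:
more effect at lower cost = dominant (no ICER), less effect at higher
cost = dominated, otherwise ICER = ΔCost/ΔQALY; ΔQALY = 0 leaves the
ICER undefined. Uncertainty: nonparametric bootstrap of clients
(n-out-of-n with replacement, B = 1000 by default, seeded
`numpy.random.default_rng`), keeping each client's (ΔCost, ΔQALY) pair
intact — unpairing would destroy the within-client correlation and
visibly change the CEAC (regression-tested). CEAC(λ) is the fraction of
replicates with net monetary benefit λ·ΔQALY − ΔCost strictly positive;
ties count as not cost-effective (a measure-zero convention made
explicit). Default λ grid: 0–100,000 € in 1,000 € steps.

## Synthetic cohort generator

What it emulates:

- **Demographics** drawn from the published baseline table (74.1% female,
  age ~ N(45.7, 17²) truncated to 18–80, education/living/employment/
  income-source category frequencies, income ~ N(669, 661²) clipped at 0).
- **Utilization**: per item and period, zero-inflated negative-binomial
  counts (gamma for direct-EUR categories). The marginal mean is the
  calibration handle: mean_units × unit cost equals the published
  category total divided by 85 clients (half-year for the pre period,
  length-proportional split over the three follow-up intervals), so the
  expected pre-period annual cost is 5,832 €/client *by construction*.
  Structural-use indicators are shared per client within a service
  category and window, so "user of day care" is a client property and
  user counts resemble the published ones; dispersion 0.6–1.5 gives the
  heavy right skew the published per-user means show (4 day-care users at
  13,530 €).
- **SF-12 responses**: two latent health scores (physical, mental) per
  client-visit — population mean + per-visit drift + client random effect
  (SD 0.8, cross-domain correlation 0.3) — discretized per item through
  fixed monotone thresholds after adding item noise (SD 0.7). The
  per-visit latent means were solved once, by a two-dimensional root
  search on a 60,000-client simulation, so the pipeline's mean utilities
  match the published trajectory (0.6051, 0.6535, 0.6602, 0.6927) and the
  MCS means match (35.4 → 44.2) under the shipped tariff; the PCS then
  lands at 41.4 → 43.7 versus the published 42.9 → 44.6 (two latent
  degrees of freedom cannot pin three summary curves; utility and MCS
  take priority, and mental health improves more than physical as
  published).
- **Dropout**: per-visit probability 0.0494 (solving (1−d)³ = 73/85 =
  0.859), independent of health by default; a switch makes the hazard
  rise for worse latent mental health. Visits are censored monotonically.

Reproducibility: one master seed; per-client substreams via
`SeedSequence.spawn`, so enlarging a cohort never changes earlier clients.

What it does *not* emulate — hence what passing tests do not show about
real data: diagnoses and the counseling process, interview-date jitter,
seasonal or secular trends, informative dropout (by default), item-level
nonresponse within an interview, and any correlation between utilization
and health state. Calibration recovery shows the pipeline is correct and
the generator matches the published *margins*, not that the study's
client-level joint distribution is reproduced.

Known systematic offset: clients without any complete follow-up (~5%)
are imputed from their pre-period rates, which exceed the post-period
rates, biasing the expected post cost up by ≈ +78 €/client (≈ +1.8%,
within the ±5% recovery band). This is a faithful consequence of the
stated imputation rule, not a calibration error, and is left uncorrected.

## Problem sizes and numerical choices

Default analyses use 85 clients and B = 1000 bootstrap replicates; the
Monte-Carlo recovery summaries average 200 independently seeded cohorts
(CEAC evaluated on the first 10). Currency is float64 EUR throughout,
rounded only at display time; visit times must be strictly increasing and
span one year; all random draws descend from a single recorded seed, and
coefficient files are identified by SHA-256 checksum in the run log.
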