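# psycea

Pre-post cost-effectiveness analysis of psychosocial outreach care, as a
tested, reusable Python pipeline.

The setting: a counseling and coordination clinic for people with mental
and psychosocial problems, evaluated from the payer perspective by
comparing the 12 months before first contact with the 12 months under
counseling (visits at baseline and 3, 6, 12 months). The package
implements every analysis stage:

- **Costing** — service-utilization records (days, visits, units) are
  multiplied with a unit-cost table (a German health/social-care preset is
  shipped, e.g. psychiatric inpatient day 386 €, GP visit 20 €);
  medication and similar categories carry direct EUR amounts. Missing
  follow-up intervals are completed by last-observation-carried-forward
  (LOCF) with interval-length scaling, the surveyed 6 pre months are
  extrapolated ×2, a flat 100 € counseling fee is added per client, and
  everything aggregates into a per-user / per-client / total report with
  normal-approximation 95% CIs.
- **Quality of life** — SF-12 responses are scored into PCS/MCS component
  summaries (published norm-based regression weights), classified into the
  six-dimensional SF-6D health state, and valued with an additive-decrement
  preference tariff; trajectories are completed by LOCF.
- **QALYs** — the post-period QALY is the area under the utility–time
  curve, Q<sub>post</sub> = ∫₀¹ u(t) dt with linear interpolation between
  visits; the pre-period QALY assumes the baseline utility was stable over
  the prior year, Q<sub>pre</sub> = u(0). ΔQALY = Q<sub>post</sub> −
  Q<sub>pre</sub>, ΔCost = C<sub>post</sub> − C<sub>pre</sub>, per client.
- **Cost-effectiveness** — client-level nonparametric bootstrap (n-out-of-n,
  pairs kept intact, default B = 1000) of the mean (ΔCost, ΔQALY);
  quadrant/ICER classification; cost-effectiveness acceptability curve
  CEAC(λ) = P(λ·ΔQALY − ΔCost > 0) over a willingness-to-pay grid.
- **Synthetic cohort** — a generator producing clients, utilization and
  SF-12 responses with the structure the analysis assumes (zero-inflated
  overdispersed utilization, latent-health-driven item responses, monotone
  dropout). A calibrated preset reproduces the published cohort margins
  (85 clients, ≈74% female, mean pre cost 5,832 €/client·year, post
  4,350 €, utility trajectory 0.605 → 0.693, 85.9% completers).

## Worked example

```sh
psycea run-all --seed 1 --outdir out/
psycea report --outdir out/
```

prints (abridged):

```
quadrant=dominant mean_delta_cost=-1808 EUR mean_delta_qaly=0.0416

    cost_item  window  n_users per_user_mean per_client_mean    total difference
    inpatient  pre12m       25        11,160           3,282  279,008   -105,174
    inpatient post12m       19         9,149           2,045  173,834   -105,174
   counseling post12m       85           100             100    8,500      8,500
      overall  pre12m       85         6,537           6,537  555,660   -153,641
      overall post12m       85         4,730           4,730  402,019   -153,641

 visit  pcs_mean  mcs_mean  utility_mean
     0   41.2288   35.8469        0.6130
     1   41.6854   41.5969        0.6511
     2   41.4594   42.0546        0.6549
     3   43.1823   44.4548        0.6786
```

One synthetic cohort of 85 clients: annual costs fall by ~1,800 € per
client while the mean utility rises from 0.613 to 0.679 (mean ΔQALY
+0.042), so the intervention is *dominant* (cheaper and more effective —
no ICER is defined) and the CEAC equals 1.0 at a willingness to pay of
50,000 €/QALY. Single cohorts scatter around the calibration targets;
averaging over many seeds recovers them (see below).

Every run writes the full set of intermediate CSVs (`expenditures.csv`,
`utilities.csv`, `qaly.csv`, `ce_plane.csv`, `ceac.csv`, …) plus
`run_log.json` with the seed, a config hash and coefficient-file
checksums; identical config and seed reproduce every file byte for byte.

The same stages are available as library functions
(`psycea.cost_records`, `psycea.qaly_deltas`, `psycea.bootstrap_ce`, …)
and as stage-wise subcommands (`simulate`, `cost`, `qol`, `qaly`, `cea`)
reading and writing the documented CSVs.

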