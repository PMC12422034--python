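# intecost

A tested, reusable pipeline for the societal cost-minimisation analysis of
**integrated versus vertical (standard) care** for HIV, hypertension (HTN)
and diabetes (DM) in a two-country cluster-randomised setting:

- **`synthetic_trial`** (`intecost.synthetic`) — generates a complete
  synthetic trial (facilities, participants, visits, dispensing records,
  patient questionnaires) with a fully known ground-truth cost structure, so
  every downstream stage is testable without any external data.
- **`money_time`** (`intecost.money`) — currency/price-year aware amounts,
  CPI inflation to 2021 prices, PPP conversion to 2021 international dollars
  (Int$1 = UGX 1310.6 = TZS 890.58), capital annuitization at 3%, and
  valuation of participant time from monthly per-capita consumption
  (30-day/8-hour default; 22-day and median-salary variants).
- **`provider_costing`** (`intecost.provider`) — top-down allocation of
  facility personnel/overhead/annuitized-capital pools over monthly patient
  visits plus bottom-up ingredients costing of medications and diagnostics,
  with the multimorbidity rules: integrated multimorbid visits with HIV are
  charged facility components at the HIV-alone rate once; integrated HTN+DM
  is charged one shared-clinic rate; standard-care multimorbid "visits" are
  composites summing one vertical visit per condition.
- **`patient_societal_costing`** (`intecost.patient`) — patient costs per
  visit from questionnaires (expenses, travel/facility/childcare time), the
  x2 time rule for standard-arm multimorbid visits, the expense-equality
  assumption for standard-arm medication/other-medical expenses, and
  societal = provider + patient totals.
- **`arm_comparison`** (`intecost.compare`) — Welch unequal-variance t-tests
  (Satterthwaite df, 95% CI, two-sided p) per country/profile/perspective
  cell plus pooled contrasts; summary-statistic mode, a pooled-variance
  option and an optional facility-level bootstrap.
- **`scale_up_budget_impact`** (`intecost.scaleup`) — national annual totals
  from annualised mean monthly costs x prevalence x condition-mix proportion
  x coverage, per-profile and overall integrated-minus-standard differences,
  and budget impact as % of current health expenditure and GDP.
- **`sensitivity_analysis`** (`intecost.sensitivity`) — +10/20/50% uplift of
  integrated personnel and overhead costs, a 3x3 two-way CI grid over costs
  and proportions for the scale-up model, and time-valuation policy variants
  with a significance concordance table.
- **`cli_reporting`** (`intecost.pipeline`, `intecost.cli`) — end-to-end
  orchestration with a run log of all assumption flags and a machine-readable
  `metrics.json` twin of every rendered table.

## CLI

```bash
intecost simulate --seed 1 --out out/sim            # synthetic trial CSVs
intecost cost --seed 1 --out out/cost               # provider cost summary
intecost compare --seed 1 --perspective societal --out out/cmp
intecost scale-up --scenario examples/scenario_uganda_demo.yaml --out out/scale
intecost sensitivity --seed 1 --scenario examples/scenario_uganda_demo.yaml --out out/sens
intecost report --seed 1 --out out/report           # full bundle
```

`report` accepts a YAML config (`--config run.yaml`) controlling the trial
size, economy parameters, scale-up scenarios and assumption flags
(`double_travel_expense`, `uplift_includes_capital`, `htn_dm_rule`,
`time_multiplier`, `equalise_expenses`, `include_questionnaires`); every
flag value in force is echoed into `run_log.txt`.

## Notes

- Published per-visit cost tables are used only as order-of-magnitude
  calibration anchors for the synthetic generator; they are not reproducible
  without participant-level data.
- Cost components are drawn from a gamma family parameterised by (mean, sd)
  (lognormal optional); sd = 0 degenerates to the exact mean, which many
  tests use as an oracle.
- All monetary arithmetic is strict about currency and price year; amounts
  are inflated to 2021 prices before PPP conversion.
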