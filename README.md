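# smokemort

Toolkit for summarizing smoking hazards from routine vital statistics in
high-income countries:

- **`riskmath`** — closed-form risk algebra: attributable fractions
  `(RR−1)/RR`, excess risk percentages, the former-vs-current
  excess-risk reduction `1 − (RR_f−1)/(RR_c−1)`, cessation-gain anchor
  tables, population life-expectancy arithmetic, percent change.
- **`attribution`** — lung-cancer-indexed indirect attribution: a
  population's never-smoker-adjusted lung cancer mortality, indexed to
  smoker/never-smoker rates from a reference prospective study, gives a
  synthetic smoking prevalence (smoking impact ratio, SIR) that drives
  population attributable fractions for other causes, with an optional
  conservative halving of non-lung excess relative risks.
- **`trends`** — decade-series mechanics: geometric annualization,
  backcasting, cumulative 1960–2020 totals (10 × the six decade-midpoint
  values), lagged cigarettes-per-death ratios (default 20-year lag), and
  share-of-total summaries.
- **`synthetic`** — seeded synthetic vital statistics with known
  current/former smoking prevalence, never-smoker baseline rates and
  cause RRs (optional Poisson noise), with ground truth retained for
  oracle and parameter-recovery tests.
- **`io` / `cli`** — CSV schemas, label normalization, run
  configuration, and the end-to-end summation report.

Bundled under `smokemort.published` are the small published-table inputs
(decade-spaced attributable-death series, 2000/2015 prevalence/amount
table, cumulative cigarette-sales totals) that feed the reports.

## CLI

```sh
smokemort attribute --mortality deaths.csv --rr rr.csv --refs refs.csv [--no-halving] --out attrib.csv
smokemort trends cumulate  --series series.csv --out cumulative.csv
smokemort trends annualize --series series.csv [--linear] --out annual.csv
smokemort trends backcast  --series series.csv --to-year 1950 --out annual.csv
smokemort trends lagratio  --sales sales.csv --country UK \
    --deaths-start 1960 --deaths-end 2020 --deaths-total 9310000 --lag 20 --out lag.csv
smokemort cessation --rr-former 1.2 --rr-current 3.0
smokemort cessation --quit-age 45 --interpolate
smokemort simulate  --config cohort.json --seed 1 --out-dir out/
smokemort summation --config run.yaml
```

CSV dialect: comma-separated UTF-8 with a header row, `.` decimal
separator, no thousands separators. Sex labels (`M`, `Females`, …) are
normalized at ingest; unknown labels are errors. Age bands are half-open
`[age_lo, age_hi)` with an empty `age_hi` meaning open-ended. Reference
rates are read per 100,000 person-years by default (`--rate-scale`).

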