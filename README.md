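# accelrel

**Reliability of accelerometer-measured sedentary time and physical activity.**

How many days does an adult need to wear a hip accelerometer before the
summary you compute — counts per minute (CPM), sedentary minutes, light or
moderate-to-vigorous activity — is a reliable estimate of their habitual
behaviour?  `accelrel` is a tested pipeline for answering that question. It
is aimed at physical-activity epidemiologists and methods researchers who
work with ActiGraph-style count data and want reproducible variance-based
reliability analyses, plus a synthetic cohort generator with known ground
truth for validating every estimator.

## What it computes

Starting from 10-second-epoch counts (one CSV per subject, up to three weeks
of continuous wear):

1. **Reduction** — epochs are summed to minutes; non-wear is flagged as runs
   of ≥ 60 min of zero counts (tolerating ≤ 2 consecutive non-zero minutes);
   worn minutes are classified by cut-points (SED < 100, LPA 100–2019,
   MPA 2020–5998, VPA ≥ 5999 cpm, MVPA = MPA + VPA); days and protocol weeks
   are summarised under configurable validity criteria (≥ 8/10/12 h per day,
   ≥ 3/4/5 valid days per week).
2. **Reliability** — a one-way random-effects variance partition per outcome
   gives the single-day intraclass correlation
   `ICC = σ²_between / (σ²_between + σ²_residual)` and the Spearman–Brown
   projection of the days needed to reach a target reliability,

   `N = ICC_t/(1−ICC_t) · (1−ICC_s)/ICC_s`  (default ICC_t = 0.80).

   Week-level estimates add absolute reliability: the standard error of
   measurement `SEM = √σ²_residual`, 95 % limits of agreement
   `LoA = SEM·√2·1.96`, and the percentage typical error `100·SEM/mean`.
   A two-way mixed model with wear time as a fixed effect (REML) gives the
   wear-adjusted versions — the adjustment that makes absolute sedentary
   time reliable.
3. **Associations** — random-intercept mixed models quantify the wear-time
   slope per outcome and weekday/weekend contrasts, plus the share of
   variance explained by day type.
4. **Agreement** — week-1-anchored Bland–Altman plots with LoA lines from
   the variance-component SEM, and an absolute-residual heteroscedasticity
   check.

A built-in generator (`accelrel.synthetic`) simulates full epoch-level
cohorts whose between-/within-subject variance components, wear-time
coupling and weekday effects are known exactly, so parameter recovery is
testable end to end.

## Worked example

Twenty simulated subjects, 21 days, seed 1 — full pipeline from the Python
API (the `accelrel run` CLI does the same):

```python
import accelrel as ar

cfg = ar.demo_config(seed=1, n_subjects=20)
cfg.output_dir = "demo_out"
res = ar.run_pipeline(cfg)
print(res["daily_reliability"].query("min_hours == 10")[
    ["outcome", "icc_s", "n_days_needed"]].round(2))
```

```
 outcome  icc_s  n_days_needed
     cpm   0.35           7.42
 sed_min   0.30           9.46
 sed_pct   0.34           7.81
 lpa_min   0.31           8.79
mvpa_min   0.31           8.89
```

A single day of monitoring carries an ICC of ~0.3 for overall activity, so
roughly 7–9 further days are needed to reach 0.80. The week-by-week table
shows why wear time matters for sedentary behaviour:

```
 outcome  adjusted  icc_s    sem  sem_pct    loa
 sed_min     False   0.61  41.01     7.29 113.68
 sed_pct     False   0.74   3.01     4.27   8.35
 sed_min      True   0.73  23.45     4.17  65.01
```

Crude weekly sedentary minutes are the least reliable outcome (ICC 0.61,
LoA ±114 min/day); adjusting for wear time nearly halves the SEM and lifts
the ICC to that of the percentage form — sedentary time should be analysed
as a percentage of wear or wear-adjusted. The wear-association table makes
the mechanism explicit: the slope of sedentary minutes on wear minutes is
0.65 (95 % CI 0.58–0.72) in this small run, while the percentage form is
attenuated to ~0 (p = 0.13).

The command-line surface mirrors the stages:

```
accelrel simulate --subjects 20 --seed 1 --out cohort/
accelrel reduce --input cohort/ --hours 10 --days 4 --out tables/
accelrel reliability --days tables/days.csv --weeks tables/weeks.csv --out tables/
accelrel agree --weeks tables/weeks.csv --outcome cpm --out tables/
accelrel run --seed 1 --out report/            # full 87-subject preset
```

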