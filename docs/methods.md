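# Methods

This note documents the statistical procedures implemented in `accelrel`,
the design of the synthetic cohort generator, the numerical choices, and
what the test suite does and does not demonstrate about real data.

## Data reduction

**Epoch → minute.** All scoring operates at minute resolution: 10-s epochs
(or any epoch length dividing 60 s) are summed to calendar minutes, and the
published cpm cut-points are applied unscaled to minute totals. This avoids
the ambiguity of dividing cut-points across epochs. Partial leading/trailing
minutes are dropped.

**Non-wear rule.** A maximal run of minutes is non-wear iff it is ≥ 60 min
long, starts and ends with a zero-count minute, and contains no stretch of
more than 2 consecutive non-zero minutes. Interruption minutes inside a
qualifying run are flagged non-wear. Two readings of the "allow ≤ 2 minutes
of non-zero counts" tolerance are defensible: per-stretch (2 consecutive
minutes, the common implementation and our default) and per-run total
(≤ 2 interruption minutes in the whole run, available as
`mode="total"`, implemented as a greedy left-to-right scan). Detection runs
over each subject's full contiguous series, so runs crossing midnight are
flagged consistently on both calendar days. Correctness of the default mode
is established against an independent exhaustive-window-scan oracle on
1,000 random sequences up to 6 h.

**Days and weeks.** Days are calendar days (midnight split). Intensity
minutes partition wear exactly; percentages are of wear time; CPM and VM
CPM divide total worn counts by wear minutes. Protocol weeks are fixed
blocks of days 1–7, 8–14, 15–21 from each subject's first recorded day (not
ISO weeks). Weekend = Saturday and Sunday. Retained-fraction denominators
are all recorded days (day filter) and all subject-weeks (week filter). The
handling of partial first/last days is deliberately naive: all calendar
days are kept and short ones are removed by the wear criteria.

## Reliability statistics

**Variance components.** The default estimator is method-of-moments from
the one-way ANOVA decomposition: `σ²_residual = MSW`,
`σ²_between = (MSB − MSW)/n0` with the unbalanced-data effective group size
`n0 = (N − Σn_i²/N)/(k − 1)`. Negative between-variance estimates are
truncated at zero and flagged. REML (random-intercept model) is available
as an option; the suite checks the two agree within 5 % on well-behaved
simulations. Moments were chosen as the default because they are exactly
verifiable against closed-form sums of squares.

**Derived quantities.** ICC = σ²_b/(σ²_b + σ²_e); days needed
`N = ICC_t/(1−ICC_t)·(1−ICC_s)/ICC_s`; `SEM = √σ²_e`;
`LoA = SEM·√2·1.96` (the LoA/SEM ratio is the constant 2.7719); percentage
typical error = 100·SEM/reference. The reference level defaults to the
sample **mean** of the weekly values rather than the median: the
conventional printed percentages reproduce from the means, and a
`reference="median"` switch covers the stricter reading of "typical error
relative to the median". Reported tables round ICC to 2 d.p. and
N/SEM/LoA to 1 d.p.; all internal arithmetic is unrounded.

**Wear adjustment.** The adjusted analysis fits
`y = μ + β·wear + b_subject + e` by REML (statsmodels `MixedLM`) and takes
`σ²_b` and `σ²_e` from that fit. Wear time is entered uncentred; centring
shifts only the intercept, not the variance components. Week-level ICC uses
all subjects contributing valid weeks; subjects with a single valid week
enter through the unbalanced formulas.

## Mixed-model associations

Wear-time slopes and weekday/weekend contrasts come from random-intercept
models fitted by REML, reported with Wald 95 % CIs. The covariate test is
the squared Wald z referred to F(1, ddf) with between-within denominator
degrees of freedom `ddf = N − k_subjects − (p_fixed − 1)`; software-specific
Satterthwaite-type corrections are not reproduced (the choice is documented
and the ddf is exposed on the fit object). The weekday dummy is coded 1 for
Monday–Friday so that higher weekday activity yields a positive
coefficient.

The week/weekend variance share treats the day-type effect as a two-level
factor: its variance over the observed weekday/weekend mix is
`p(1−p)·β²` with `p` the weekday fraction, and the ratio divides by
`σ²_b + p(1−p)β² + σ²_e` from the same wear-adjusted fit. A moment
cross-check (components reassembling the sample variance of the
wear-adjusted outcome within 5 %) guards this construction.

## Bland–Altman agreement

Pairs are anchored on week 1 (week 1 vs 2, week 1 vs 3; week 2 vs 3 is
available but not plotted by default, matching the usual presentation). The
LoA half-width is taken from the variance-component SEM of the weekly
means, not from the pair SD, so the agreement plot and the reliability
table share one error term; with three weeks per subject the two
constructions agree closely. Whether the crude or wear-adjusted SEM draws
the lines is switchable; crude is the default. Heteroscedasticity is
assessed by OLS regression of |difference| on the pair mean with a
two-sided t test at α = .05 — a formalisation of what is usually a visual
judgement.

## Synthetic cohort generator

**Design.** The generator emulates a three-week free-living monitoring
study in adults. Defaults: 87 subjects × 21 days starting on a Monday;
~800 worn minutes on a normal day (subject SD 40, week SD 30, day SD 90)
with a 30 % chance of a "low-wear day" (Uniform 300–590 min), calibrated so
roughly 18/31/46 % of days fail the ≥ 8/10/12 h criteria; daily outcome
means SED 564, LPA 183, MVPA 66 min and CPM 486; variance components give
single-day ICCs of ≈ 0.2–0.55 across outcomes and weekly ICCs ≈ 0.6–0.75;
wear-time slopes 0.709 (SED) and 0.047 (MVPA); weekend shifts −78.4 (CPM),
+18.2 (SED), −11.3 (MVPA). CPM and MVPA shocks are correlated (ρ = 0.6) so
low-activity days are also low-intensity days. The CPM/VM scale ratio
(≈ 1.80) follows from fixed axis-2/axis-3 proportions of the vertical axis.

**Closure.** Because intensity classification partitions worn time,
SED + LPA + MVPA must equal wear exactly, so only three of the four
behavioural quantities can follow free generating equations. SED, MVPA,
CPM (and wear itself) follow their configured linear mixed models exactly;
**LPA is the closure outcome** (`lpa = wear − sed − mvpa`). Its induced
wear slope is `1 − γ_SED − γ_MVPA ≈ 0.244` and its variance components are
inherited rather than configured — parameter-recovery guarantees therefore
apply to CPM, SED, MVPA and wear, and `true_single_day_icc` returns the
nominal configured ratio for LPA with a documented caveat.

**Minute and epoch realisation.** Day totals are laid down as shuffled
bouts with geometric lengths (mean 20/8/5/2 min for SED/LPA/MPA/VPA — the
bout structure is a modelling convenience, not an empirical claim). Each
state's minutes draw counts inside its cpm band around a state level; the
light-activity level is solved per day (within band bounds, falling back to
the other states' levels) so the day's total counts hit the generated CPM,
and draws are nudged to the exact state total so realised CPM matches the
latent value to ≲ 0.2 cpm. Minutes split into 10-s epochs by a symmetric
multinomial, so epoch counts are non-negative integers summing to the
minute count. Non-wear is inserted as all-zero blocks ≥ 60 min (overnight
blocks at the day edges plus Poisson-rate daytime removals), occasionally
carrying a 1–2-min non-zero spike that the detection tolerance must absorb.
Worn sedentary minutes are floored at 1 count so genuine wear never mimics
device-off; consequently reduction recovers the generated wear and
intensity minutes *exactly*, which the suite asserts.

**What the generator does not emulate.** Raw 30 Hz signals and the count
filter chain; device nonlinearity or between-device differences; diurnal
and seasonal structure; autocorrelated or skewed day-level residuals (the
Normal generating model is an assumption — real MVPA distributions are
right-skewed); behaviour-dependent non-wear (missingness is independent of
the outcomes given wear time). Passing parameter-recovery tests therefore
shows the estimators are correct under the stated variance-components
model, not that real accelerometer data satisfies that model.

## Problem sizes used in the tests

Parameter-recovery and adjustment-direction checks run on the generator's
day-level stage (87 × 21; 50 and 40 seeded replicates respectively), which
is exact for the quantities involved since the epoch path reproduces the
day stage bit-for-bit for wear and intensity minutes (asserted separately
on a 5-subject cohort). The full epoch-level pipeline is exercised at the
reference scale (87 subjects, ~15.7 M epochs) once in the acceptance suite
and at 10–20 subjects elsewhere. Monte-Carlo tolerances follow the binomial
or sampling error of each check at those sizes.

## Known limitations

* SPSS-specific mixed-model conventions (denominator df, its exact
  two-way variance partition) are approximated by the documented choices
  above; estimates agree to sampling precision on clean simulations but
  software-exact equality is not claimed.
* ICC confidence intervals are not implemented.
* The greedy scan of the `mode="total"` non-wear variant is order-dependent
  in rare tie cases; only the default consecutive mode carries an
  oracle-equivalence guarantee.
* Zero-wear days yield NaN intensity summaries and are excluded by any
  sensible criterion, but a cohort consisting entirely of such days will
  fail estimation with an explicit error rather than a result.
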