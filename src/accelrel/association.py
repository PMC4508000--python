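"""Mixed-model associations between wear time, day type and daily outcomes.

Random-intercept (per subject) linear mixed models, fitted by REML, quantify

* how strongly each daily outcome tracks daily wear time (a large positive
  slope for sedentary minutes is the structural reason absolute sedentary
  time is unreliable without wear-time correction),
* weekday/weekend differences, adjusted for wear time, and
* the share of total outcome variance attributable to the week/weekend
  day-type contrast.

Wald 95% confidence intervals are reported; the covariate test statistic is
the squared Wald z referred to an F(1, ddf) distribution with
between-within denominator degrees of freedom ``n_obs - n_subjects -
(n_fixed - 1)``, a conventional approximation for level-1 covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .reliability import EstimationError

logger = logging.getLogger(__name__)


@dataclass
class MixedModelFit:
    """A single fixed-effect estimate from a random-intercept model."""

    beta: float
    ci_low: float
    ci_high: float
    f_stat: float
    p_value: float
    n_obs: int
    n_subjects: int
    ddf: int
    outcome_name: str
    covariate_name: str


def _fit(y, X, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(np.asarray(y, dtype=float), X, groups=np.asarray(groups))
        res = model.fit(reml=True)
    if not res.converged:
        raise EstimationError("mixed-model fit did not converge")
    return res


def _wald_fit(res, index: int, n_obs: int, n_subjects: int, k_fixed: int,
              outcome: str, covariate: str) -> MixedModelFit:
    beta = float(np.asarray(res.fe_params)[index])
    se = float(np.asarray(res.bse_fe)[index])
    z = beta / se
    ddf = n_obs - n_subjects - (k_fixed - 1)
    if ddf <= 0:
        raise EstimationError("non-positive denominator degrees of freedom")
    f = z**2
    p = float(stats.f.sf(f, 1, ddf))
    half = 1.96 * se
    return MixedModelFit(
        beta=beta,
        ci_low=beta - half,
        ci_high=beta + half,
        f_stat=f,
        p_value=p,
        n_obs=n_obs,
        n_subjects=n_subjects,
        ddf=ddf,
        outcome_name=outcome,
        covariate_name=covariate,
    )


def wear_association(days: pd.DataFrame, outcome: str) -> MixedModelFit:
    """Slope of a daily outcome on daily wear minutes.

    Fits ``outcome = mu + beta * wear_minutes + b_subject + e`` by REML on
    the supplied (already validity-filtered) day table and returns the wear
    slope with Wald CI and F test.
    """
    df = days.dropna(subset=[outcome, "wear_minutes"])
    if df["subject_id"].nunique() < 2:
        raise EstimationError("need at least 2 subjects")
    x = df["wear_minutes"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise EstimationError("wear time is constant; slope not identified")
    X = np.column_stack([np.ones_like(x), x])
    res = _fit(df[outcome], X, df["subject_id"])
    return _wald_fit(
        res, 1, len(df), df["subject_id"].nunique(), 2, outcome, "wear_minutes"
    )


def weekday_weekend_effect(days: pd.DataFrame, outcome: str) -> MixedModelFit:
    """Weekday-vs-weekend contrast adjusted for wear time.

    Adds a weekday dummy (1 = Monday-Friday) to the wear-time model and
    returns the dummy's estimate, so a positive coefficient means higher
    values on weekdays.  Subjects with only one day type still contribute.
    """
    df = days.dropna(subset=[outcome, "wear_minutes"])
    weekday = (~df["weekend"].astype(bool)).to_numpy(dtype=float)
    if len(np.unique(weekday)) < 2:
        raise EstimationError("weekday dummy has no variation")
    x = df["wear_minutes"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x, weekday])
    res = _fit(df[outcome], X, df["subject_id"])
    return _wald_fit(
        res, 2, len(df), df["subject_id"].nunique(), 3, outcome, "weekday"
    )


def weekweekend_variance_ratio(days: pd.DataFrame, outcome: str) -> float:
    """Share of total variance explained by the week/weekend contrast.

    With wear time held fixed, the day-type variance is the variance of the
    fitted day-type effect over the observed weekday/weekend mix,
    ``p * (1 - p) * beta^2``; the ratio divides it by the total
    ``sigma2_between + sigma2_daytype + sigma2_residual`` from the same REML
    fit.
    """
    df = days.dropna(subset=[outcome, "wear_minutes"])
    weekday = (~df["weekend"].astype(bool)).to_numpy(dtype=float)
    if len(np.unique(weekday)) < 2:
        raise EstimationError("weekday dummy has no variation")
    x = df["wear_minutes"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x, weekday])
    res = _fit(df[outcome], X, df["subject_id"])
    beta2 = float(np.asarray(res.fe_params)[2])
    p = float(weekday.mean())
    sigma2_dt = p * (1 - p) * beta2**2
    sigma2_b = float(np.asarray(res.cov_re)[0, 0])
    sigma2_e = float(res.scale)
    return sigma2_dt / (sigma2_b + sigma2_dt + sigma2_e)


def association_table(days: pd.DataFrame, outcomes) -> pd.DataFrame:
    """Wear-time association table: one row per outcome column."""
    rows = []
    for outcome in outcomes:
        fit = wear_association(days, outcome)
        rows.append(
            {
                "outcome": outcome,
                "beta": fit.beta,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "f": fit.f_stat,
                "p": fit.p_value,
                "n_obs": fit.n_obs,
                "n_subjects": fit.n_subjects,
            }
        )
    return pd.DataFrame(rows)
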