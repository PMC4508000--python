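"""Variance-component reliability statistics.

Implements the quantities used to judge how many days (or weeks) of
accelerometer monitoring are needed for a reliable estimate of habitual
behaviour:

* one-way random-effects variance partitioning (method-of-moments ANOVA
  estimators with the unbalanced-data effective group size, or REML),
* the intraclass correlation ICC = sigma^2_between / sigma^2_total,
* the Spearman-Brown prophecy formula for the number of repeated
  measurement days N needed to reach a target reliability ICC_t,
* absolute reliability: SEM = sqrt(residual variance), 95% limits of
  agreement LoA = SEM * sqrt(2) * 1.96, and the percentage typical error
  100 * SEM / reference level,
* wear-time-adjusted variance components from a mixed model with wear time
  as a fixed effect (REML).

Table builders assemble these into the day-level reliability grid
(outcome x hour criterion) and the week-by-week reliability table with and
without wear-time adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .reduction import OUTCOME_COLUMNS, WearCriteria, filter_valid_days

logger = logging.getLogger(__name__)

#: LoA half-width per unit SEM: sqrt(2) * 1.96.
LOA_FACTOR = float(np.sqrt(2.0) * 1.96)


class EstimationError(RuntimeError):
    """Raised when a variance-component estimate cannot be formed."""


@dataclass
class VarianceComponents:
    """Between-subject and residual variance estimates.

    ``n0`` is the effective group size for unbalanced data,
    ``(n_obs - sum(n_i^2)/n_obs) / (n_groups - 1)``; it equals the common
    group size when the design is balanced.  ``sigma2_extra`` carries an
    optional third component (e.g. a week/weekend day-type variance).
    ``truncated`` records whether a negative method-of-moments
    between-variance was floored at zero.
    """

    sigma2_between: float
    sigma2_residual: float
    n_groups: int
    n_obs: int
    n0: float
    sigma2_extra: float = 0.0
    covariate_adjusted: bool = False
    beta: float | None = None
    truncated: bool = False


@dataclass
class ReliabilityEstimate:
    """Bundle of relative and absolute reliability measures for one outcome."""

    icc_s: float
    sem: float
    sem_pct: float
    loa: float
    n_days_needed: float
    icc_t: float
    reference_level: float


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

def _as_arrays(values, groups):
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    mask = ~np.isnan(y)
    return y[mask], g[mask]


def oneway_components(values, groups, method: str = "moments") -> VarianceComponents:
    """One-way random-effects variance components.

    ``method="moments"`` (default) uses the ANOVA mean squares with the
    unbalanced-data effective group size n0: the residual variance is the
    within-group mean square and the between variance is
    ``(MSB - MSW) / n0``, floored at zero.  ``method="reml"`` fits a random-
    intercept model by restricted maximum likelihood instead.
    """
    y, g = _as_arrays(values, groups)
    labels, counts = np.unique(g, return_counts=True)
    k = len(labels)
    n = len(y)
    if k < 2:
        raise EstimationError("need at least 2 groups")
    if not np.any(counts >= 2):
        raise EstimationError("need at least one group with >= 2 observations")

    if method == "reml":
        res = _fit_mixedlm(y, np.ones((n, 1)), g)
        return VarianceComponents(
            sigma2_between=float(np.asarray(res.cov_re)[0, 0]),
            sigma2_residual=float(res.scale),
            n_groups=k,
            n_obs=n,
            n0=_effective_group_size(counts),
            covariate_adjusted=False,
        )
    if method != "moments":
        raise ValueError(f"unknown method: {method!r}")

    grand = y.mean()
    means = np.array([y[g == lab].mean() for lab in labels])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((y - means[np.searchsorted(labels, g)]) ** 2))
    msb = ssb / (k - 1)
    dfw = n - k
    if dfw <= 0:
        raise EstimationError("no residual degrees of freedom (all groups singletons)")
    msw = ssw / dfw
    n0 = _effective_group_size(counts)
    s2b = (msb - msw) / n0
    truncated = s2b < 0
    if truncated:
        logger.warning("negative between-subject variance estimate truncated to 0")
        s2b = 0.0
    return VarianceComponents(
        sigma2_between=s2b,
        sigma2_residual=msw,
        n_groups=k,
        n_obs=n,
        n0=n0,
        truncated=truncated,
    )


def _effective_group_size(counts: np.ndarray) -> float:
    n = counts.sum()
    k = len(counts)
    return float((n - np.sum(counts**2) / n) / (k - 1))


def _fit_mixedlm(y, X, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        res = model.fit(reml=True)
    if not res.converged:
        raise EstimationError("mixed-model REML fit did not converge")
    return res


def adjusted_components(values, groups, covariate) -> VarianceComponents:
    """Variance components with a fixed covariate (typically wear time).

    Fits ``value = mu + beta * covariate + b_group + e`` by REML and returns
    the two variance estimates with ``covariate_adjusted=True`` and the
    fitted slope in ``beta``.  A covariate without variation falls back to
    the unadjusted one-way components with a warning.
    """
    y, g = _as_arrays(values, groups)
    x = np.asarray(covariate, dtype=float)[~np.isnan(np.asarray(values, dtype=float))]
    if len(x) != len(y):
        raise ValueError("covariate must be observed for every observation")
    if np.ptp(x) == 0:
        logger.warning("covariate has zero variance; returning unadjusted components")
        return oneway_components(y, g)
    X = np.column_stack([np.ones_like(x), x])
    res = _fit_mixedlm(y, X, g)
    labels, counts = np.unique(g, return_counts=True)
    return VarianceComponents(
        sigma2_between=float(np.asarray(res.cov_re)[0, 0]),
        sigma2_residual=float(res.scale),
        n_groups=len(labels),
        n_obs=len(y),
        n0=_effective_group_size(counts),
        covariate_adjusted=True,
        beta=float(np.asarray(res.fe_params)[1]),
    )


# ---------------------------------------------------------------------------
# Derived reliability quantities
# ---------------------------------------------------------------------------

def icc_single(vc: VarianceComponents) -> float:
    """ICC = sigma2_between / (sigma2_between + sigma2_extra + sigma2_residual)."""
    total = vc.sigma2_between + vc.sigma2_extra + vc.sigma2_residual
    if total <= 0:
        raise EstimationError("zero total variance; ICC undefined")
    return vc.sigma2_between / total


def spearman_brown_days(icc_s: float, icc_t: float = 0.80) -> float:
    """Days of measurement needed to lift a single-day ICC to a target.

    N = ICC_t/(1-ICC_t) * (1-ICC_s)/ICC_s, returned unrounded.  Degenerate
    single-day reliabilities (0 or 1) have no finite/meaningful answer and
    raise ``ValueError``.
    """
    if not (0 < icc_s < 1):
        raise ValueError("icc_s must lie strictly between 0 and 1")
    if not (0 < icc_t < 1):
        raise ValueError("icc_t must lie strictly between 0 and 1")
    return icc_t / (1 - icc_t) * (1 - icc_s) / icc_s


def sem_from_components(vc: VarianceComponents) -> float:
    """Standard error of measurement: sqrt(residual variance)."""
    return float(np.sqrt(vc.sigma2_residual))


def loa_from_sem(sem: float) -> float:
    """95% limits-of-agreement half-width: SEM * sqrt(2) * 1.96."""
    if sem < 0:
        raise ValueError("sem must be >= 0")
    return sem * LOA_FACTOR


def typical_error_pct(sem: float, reference_level: float) -> float:
    """SEM as a percentage of a reference outcome level."""
    if reference_level <= 0:
        raise ValueError("reference_level must be positive")
    return 100.0 * sem / reference_level


def reliability_estimate(
    vc: VarianceComponents,
    reference_level: float,
    icc_t: float = 0.80,
) -> ReliabilityEstimate:
    """Assemble ICC, SEM, SEM%, LoA and days-needed from fitted components."""
    icc = icc_single(vc)
    sem = sem_from_components(vc)
    if 0 < icc < 1:
        n_needed = spearman_brown_days(icc, icc_t)
    else:
        n_needed = float("nan")
    return ReliabilityEstimate(
        icc_s=icc,
        sem=sem,
        sem_pct=typical_error_pct(sem, reference_level) if reference_level > 0 else float("nan"),
        loa=loa_from_sem(sem),
        n_days_needed=n_needed,
        icc_t=icc_t,
        reference_level=reference_level,
    )


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def reliability_table(
    days: pd.DataFrame,
    hour_criteria=(8, 10, 12),
    outcomes=OUTCOME_COLUMNS,
    icc_t: float = 0.80,
) -> pd.DataFrame:
    """Single-day reliability grid: ICC_s and days-needed per outcome x criterion.

    For each hour criterion the day table is filtered to valid days, then a
    one-way variance partition per outcome yields ICC_s and the
    Spearman-Brown days-needed N.  Cells with fewer than 2 usable subjects
    are flagged with NaN estimates.
    """
    rows = []
    for h in hour_criteria:
        valid, frac = filter_valid_days(days, WearCriteria(min_hours_per_day=h, min_days_per_week=1))
        for outcome in outcomes:
            rec = {
                "outcome": outcome,
                "min_hours": h,
                "n_days": len(valid),
                "retained_frac": frac,
            }
            try:
                vc = oneway_components(valid[outcome], valid["subject_id"])
                icc = icc_single(vc)
                rec["icc_s"] = icc
                rec["n_days_needed"] = (
                    spearman_brown_days(icc, icc_t) if 0 < icc < 1 else float("nan")
                )
            except (EstimationError, ValueError) as err:
                logger.warning("reliability cell %s @ >=%dh failed: %s", outcome, h, err)
                rec["icc_s"] = float("nan")
                rec["n_days_needed"] = float("nan")
            rows.append(rec)
    return pd.DataFrame(rows)


def weekly_reliability_table(
    weeks: pd.DataFrame,
    adjust: bool = False,
    outcomes=OUTCOME_COLUMNS,
    icc_t: float = 0.80,
    reference: str = "mean",
) -> pd.DataFrame:
    """Week-by-week reliability per outcome from weekly means.

    Crude estimates come from a one-way random-effects partition of the
    weekly means; with ``adjust=True`` the variance components come from a
    mixed model with weekly mean wear time as a fixed effect.  ``reference``
    selects the sample ``"mean"`` (default) or ``"median"`` weekly value as
    the denominator of the percentage typical error; the two differ little
    for roughly symmetric outcomes and the mean reproduces the conventional
    reporting.
    """
    counts = weeks.groupby("subject_id").size()
    if (counts >= 2).sum() < 2:
        raise EstimationError("need >= 2 subjects with >= 2 valid weeks")
    rows = []
    for outcome in outcomes:
        y = weeks[outcome]
        ref = float(y.mean()) if reference == "mean" else float(y.median())
        if adjust:
            vc = adjusted_components(y, weeks["subject_id"], weeks["wear_minutes"])
        else:
            vc = oneway_components(y, weeks["subject_id"])
        est = reliability_estimate(vc, ref, icc_t)
        rows.append(
            {
                "outcome": outcome,
                "adjusted": adjust,
                "icc_s": est.icc_s,
                "sem": est.sem,
                "sem_pct": est.sem_pct,
                "loa": est.loa,
                "n_weeks_needed": est.n_days_needed,
                "reference_level": est.reference_level,
                "n_weeks": vc.n_obs,
                "n_subjects": vc.n_groups,
            }
        )
    return pd.DataFrame(rows)
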