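"""Reduction of epoch-level accelerometer counts to daily and weekly summaries.

This module takes 10-second-epoch count series from hip-worn ActiGraph-style
devices and produces the per-day and per-week summary tables on which all
reliability statistics are computed.  The processing chain is:

1. :func:`aggregate_to_minutes` — sum epochs to calendar minutes, the
   resolution at which the non-wear rule and cut-points are defined.
2. :func:`detect_nonwear` — flag non-wear as runs of >= 60 minutes of zero
   counts, tolerating short (<= 2 consecutive minutes) non-zero
   interruptions, the rule widely used for free-living adult data.
3. :func:`classify_minute` — intensity classification of worn minutes by
   counts-per-minute (cpm) cut-points: sedentary < 100 cpm, light 100-2019,
   moderate 2020-5998, vigorous >= 5999 cpm.
4. :func:`summarize_days` / :func:`summarize_weeks` — daily totals (wear
   minutes, CPM, vector-magnitude CPM, intensity minutes and percentages of
   wear time) and weekly means over days that satisfy configurable wear-time
   validity criteria (>= 8/10/12 h per day, >= 3/4/5 valid days per week).

All tabular interchange uses plain :class:`pandas.DataFrame` objects with the
column names documented on each function, and plain CSV on disk.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTENSITY_LABELS = ("sed", "lpa", "mpa", "vpa")

#: Outcome columns analysed throughout the package (daily and weekly tables).
OUTCOME_COLUMNS = (
    "cpm",
    "vm_cpm",
    "sed_min",
    "sed_pct",
    "lpa_min",
    "lpa_pct",
    "mvpa_min",
    "mvpa_pct",
)

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class CutPointSet:
    """Intensity cut-points on vertical-axis counts per minute.

    Bands are half-open: sedentary [0, sed_upper), light [sed_upper,
    lpa_upper), moderate [lpa_upper, mpa_upper), vigorous [mpa_upper, inf).
    Defaults give the conventional adult bands <100 / 100-2019 / 2020-5998 /
    >=5999 cpm.
    """

    sed_upper: float = 100.0
    lpa_upper: float = 2020.0
    mpa_upper: float = 5999.0

    def __post_init__(self) -> None:
        if not (0 < self.sed_upper < self.lpa_upper < self.mpa_upper):
            raise ValueError(
                "cut-points must satisfy 0 < sed_upper < lpa_upper < mpa_upper"
            )

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.sed_upper, self.lpa_upper, self.mpa_upper])


DEFAULT_CUTS = CutPointSet()


@dataclass(frozen=True)
class WearCriteria:
    """Validity thresholds: minimum wear hours per day and valid days per week."""

    min_hours_per_day: float = 10.0
    min_days_per_week: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.min_hours_per_day <= 24):
            raise ValueError("min_hours_per_day must be in (0, 24]")
        if not (1 <= self.min_days_per_week <= 7):
            raise ValueError("min_days_per_week must be in [1, 7]")

    @property
    def min_wear_minutes(self) -> float:
        return 60.0 * self.min_hours_per_day


# ---------------------------------------------------------------------------
# Epoch -> minute aggregation
# ---------------------------------------------------------------------------

def aggregate_to_minutes(series) -> pd.DataFrame:
    """Sum a contiguous epoch series to calendar minutes.

    Parameters
    ----------
    series : EpochSeries
        A single subject's contiguous, uniformly spaced epoch counts whose
        epoch length divides 60 s.

    Returns
    -------
    DataFrame with columns ``subject_id, timestamp, axis1, vm`` and one row
    per whole calendar minute; partial leading/trailing minutes are dropped.
    """
    step = int(series.epoch_seconds)
    if step <= 0 or 60 % step != 0:
        raise ValueError("epoch_seconds must be a positive divisor of 60")
    per_min = 60 // step

    start = pd.Timestamp(series.start_time)
    offset_sec = start.second
    # epochs to skip so the first kept epoch starts a whole minute
    if offset_sec % step != 0:
        raise ValueError("series start is not aligned to the epoch grid")
    lead = ((60 - offset_sec) % 60) // step

    a1 = np.asarray(series.counts_axis1)
    vm = np.asarray(series.vm, dtype=float)
    n_min = (len(a1) - lead) // per_min
    if n_min <= 0:
        return pd.DataFrame(columns=["subject_id", "timestamp", "axis1", "vm"])
    stop = lead + n_min * per_min
    axis1_min = a1[lead:stop].reshape(n_min, per_min).sum(axis=1)
    vm_min = vm[lead:stop].reshape(n_min, per_min).sum(axis=1)

    t0 = start + pd.Timedelta(seconds=lead * step)
    timestamps = t0 + pd.to_timedelta(np.arange(n_min), unit="min")
    return pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "timestamp": timestamps,
            "axis1": axis1_min.astype(np.int64),
            "vm": vm_min,
        }
    )


def cohort_to_minutes(series_list) -> pd.DataFrame:
    """Aggregate a collection of :class:`EpochSeries` to one minute table."""
    frames = [aggregate_to_minutes(s) for s in series_list]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Non-wear detection
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """Run-length encode a boolean array -> (values, starts, lengths)."""
    n = len(mask)
    if n == 0:
        return np.empty(0, bool), np.empty(0, int), np.empty(0, int)
    change = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return mask[starts], starts, lengths


def nonwear_mask(
    counts: np.ndarray,
    window_min: int = 60,
    tolerance_min: int = 2,
    mode: str = "consecutive",
) -> np.ndarray:
    """Boolean non-wear flags for a contiguous minute-count sequence.

    A maximal run of minutes is non-wear iff it is at least ``window_min``
    long, starts and ends with a zero-count minute, and contains no stretch
    of more than ``tolerance_min`` consecutive non-zero minutes
    (``mode="consecutive"``, the default reading of the "allowing for <= 2
    minutes of non-zero counts" rule).  Interruption minutes inside a
    qualifying run are themselves flagged non-wear.

    ``mode="total"`` instead caps the *total* interruption minutes per run at
    ``tolerance_min`` using a greedy left-to-right scan; this alternative
    reading is provided as a switch but is not the default.
    """
    counts = np.asarray(counts)
    if window_min < 1 or tolerance_min < 0:
        raise ValueError("window_min >= 1 and tolerance_min >= 0 required")
    n = len(counts)
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    nz = counts != 0

    if mode == "consecutive":
        vals, starts, lengths = _runs(nz)
        # breakers: non-zero runs longer than the tolerance
        breaker = vals & (lengths > tolerance_min)
        seg_start = 0
        boundaries = list(np.flatnonzero(breaker)) + [len(vals)]
        for b in boundaries:
            if b > seg_start:
                # segment of runs seg_start..b-1 contains only zeros and
                # short interruptions; trim any non-zero runs at its ends
                lo, hi = seg_start, b - 1
                while lo <= hi and vals[lo]:
                    lo += 1
                while hi >= lo and vals[hi]:
                    hi -= 1
                if hi >= lo:
                    i0 = starts[lo]
                    i1 = starts[hi] + lengths[hi]
                    if i1 - i0 >= window_min:
                        flags[i0:i1] = True
            seg_start = b + 1
    elif mode == "total":
        i = 0
        while i < n:
            if nz[i]:
                i += 1
                continue
            used = 0
            consec = 0
            last_zero = i
            j = i
            while j < n:
                if nz[j]:
                    consec += 1
                    used += 1
                    if consec > tolerance_min or used > tolerance_min:
                        break
                else:
                    consec = 0
                    last_zero = j
                j += 1
            if last_zero - i + 1 >= window_min:
                flags[i : last_zero + 1] = True
            i = last_zero + 1
    else:
        raise ValueError(f"unknown interruption mode: {mode!r}")
    return flags


def detect_nonwear(
    minutes: pd.DataFrame,
    window_min: int = 60,
    tolerance_min: int = 2,
    mode: str = "consecutive",
) -> pd.DataFrame:
    """Add a ``wear_flag`` column to a minute table.

    Detection runs over each subject's full contiguous minute sequence, so
    non-wear runs that cross midnight are flagged consistently on both
    sides.  The input must be sorted by subject and timestamp.
    """
    out = minutes.copy()
    wear = np.ones(len(out), dtype=bool)
    for _, idx in out.groupby("subject_id", sort=False).indices.items():
        counts = out["axis1"].to_numpy()[idx]
        nw = nonwear_mask(counts, window_min, tolerance_min, mode)
        wear[idx] = ~nw
    out["wear_flag"] = wear
    return out


# ---------------------------------------------------------------------------
# Intensity classification and daily summaries
# ---------------------------------------------------------------------------

def classify_minute(cpm, cuts: CutPointSet = DEFAULT_CUTS):
    """Intensity label(s) for worn-minute count values.

    Accepts a scalar or array of per-minute vertical-axis counts and returns
    the corresponding label(s) from ``("sed", "lpa", "mpa", "vpa")`` using
    half-open bands.  Negative counts raise ``ValueError``.
    """
    arr = np.asarray(cpm)
    if np.any(arr < 0):
        raise ValueError("negative counts cannot be classified")
    idx = np.searchsorted(cuts.edges, arr, side="right")
    if np.isscalar(cpm) or arr.ndim == 0:
        return INTENSITY_LABELS[int(idx)]
    return np.asarray(INTENSITY_LABELS, dtype=object)[idx]


def summarize_days(minutes: pd.DataFrame, cuts: CutPointSet = DEFAULT_CUTS) -> pd.DataFrame:
    """Daily summaries from a wear-flagged minute table.

    Returns one row per subject-day present in ``minutes`` with columns::

        subject_id, date, day_index, week_index, weekend, wear_minutes,
        cpm, vm_cpm, sed_min, lpa_min, mpa_min, vpa_min, mvpa_min,
        sed_pct, lpa_pct, mvpa_pct, valid_ge_8h, valid_ge_10h, valid_ge_12h

    Intensity minutes are computed over worn minutes only and sum exactly to
    ``wear_minutes``; percentages are of wear time.  A day with zero wear
    minutes keeps its row with ``wear_minutes == 0`` and NaN intensities,
    flagged invalid at every hour criterion.  ``week_index`` counts fixed
    7-day protocol blocks (1-7, 8-14, ...) from each subject's first
    recorded day; ``weekend`` marks Saturdays and Sundays.
    """
    if "wear_flag" not in minutes.columns:
        raise ValueError("minutes must carry a wear_flag column (run detect_nonwear)")
    df = minutes[["subject_id", "timestamp", "axis1", "vm", "wear_flag"]].copy()
    df["date"] = df["timestamp"].dt.normalize()

    # full day index (keeps zero-wear days)
    day_key = df[["subject_id", "date"]].drop_duplicates()

    worn = df[df["wear_flag"]].copy()
    worn["label"] = classify_minute(worn["axis1"].to_numpy(), cuts)

    g = worn.groupby(["subject_id", "date"], sort=True)
    base = g.agg(
        wear_minutes=("axis1", "size"),
        total_axis1=("axis1", "sum"),
        total_vm=("vm", "sum"),
    )
    label_min = (
        worn.pivot_table(
            index=["subject_id", "date"],
            columns="label",
            values="axis1",
            aggfunc="size",
            fill_value=0,
        )
        .reindex(columns=list(INTENSITY_LABELS), fill_value=0)
    )
    label_min.columns = [f"{c}_min" for c in label_min.columns]

    days = day_key.set_index(["subject_id", "date"]).join(base).join(label_min)
    days["wear_minutes"] = days["wear_minutes"].fillna(0).astype(int)
    for c in ("sed_min", "lpa_min", "mpa_min", "vpa_min"):
        days[c] = days[c].astype(float)
    days["mvpa_min"] = days["mpa_min"] + days["vpa_min"]

    with np.errstate(invalid="ignore", divide="ignore"):
        wm = days["wear_minutes"].where(days["wear_minutes"] > 0)
        days["cpm"] = days["total_axis1"] / wm
        days["vm_cpm"] = days["total_vm"] / wm
        days["sed_pct"] = 100.0 * days["sed_min"] / wm
        days["lpa_pct"] = 100.0 * days["lpa_min"] / wm
        days["mvpa_pct"] = 100.0 * days["mvpa_min"] / wm
    days.loc[days["wear_minutes"] == 0, ["sed_min", "lpa_min", "mpa_min", "vpa_min", "mvpa_min"]] = np.nan

    for h in (8, 10, 12):
        days[f"valid_ge_{h}h"] = days["wear_minutes"] >= 60 * h

    days = days.drop(columns=["total_axis1", "total_vm"]).reset_index()
    days["weekend"] = days["date"].dt.weekday >= 5
    first = days.groupby("subject_id")["date"].transform("min")
    days["day_index"] = (days["date"] - first).dt.days + 1
    days["week_index"] = (days["day_index"] - 1) // 7 + 1
    cols = [
        "subject_id", "date", "day_index", "week_index", "weekend",
        "wear_minutes", "cpm", "vm_cpm",
        "sed_min", "lpa_min", "mpa_min", "vpa_min", "mvpa_min",
        "sed_pct", "lpa_pct", "mvpa_pct",
        "valid_ge_8h", "valid_ge_10h", "valid_ge_12h",
    ]
    return days[cols].sort_values(["subject_id", "date"]).reset_index(drop=True)


def filter_valid_days(days: pd.DataFrame, criteria: WearCriteria):
    """Retain days meeting the hour criterion.

    Returns ``(subset, retained_fraction)``; the fraction is NaN on empty
    input.  The denominator is every recorded protocol day.
    """
    if len(days) == 0:
        return days.copy(), float("nan")
    keep = days["wear_minutes"] >= criteria.min_wear_minutes
    subset = days[keep].reset_index(drop=True)
    return subset, len(subset) / len(days)


def summarize_weeks(days: pd.DataFrame, criteria: WearCriteria):
    """Weekly means over valid days, for weeks with enough valid days.

    Days are first filtered by the hour criterion; protocol weeks with fewer
    than ``criteria.min_days_per_week`` valid days are dropped.  Returns
    ``(weeks, retained_fraction)`` where the fraction's denominator is every
    subject-week present in ``days`` (valid or not).

    The weekly table has columns ``subject_id, week_index, n_valid_days``
    plus the mean of ``wear_minutes`` and of every outcome column over the
    week's valid days.
    """
    n_subject_weeks = len(days[["subject_id", "week_index"]].drop_duplicates())
    valid, _ = filter_valid_days(days, criteria)
    if len(valid) == 0:
        empty = pd.DataFrame(
            columns=["subject_id", "week_index", "n_valid_days", "wear_minutes", *OUTCOME_COLUMNS]
        )
        return empty, float("nan") if n_subject_weeks == 0 else 0.0
    value_cols = ["wear_minutes", *OUTCOME_COLUMNS]
    g = valid.groupby(["subject_id", "week_index"], sort=True)
    weeks = g[value_cols].mean()
    weeks.insert(0, "n_valid_days", g.size())
    weeks = weeks[weeks["n_valid_days"] >= criteria.min_days_per_week].reset_index()
    frac = len(weeks) / n_subject_weeks if n_subject_weeks else float("nan")
    return weeks, frac


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_epoch_csv(path):
    """Read one subject's epoch CSV (subject_id, timestamp, axis1, axis2, axis3).

    The per-epoch vector magnitude is reconstructed as the Euclidean norm of
    the three axis counts.  Returns an :class:`accelrel.synthetic.EpochSeries`.
    """
    from .synthetic import EpochSeries  # local import to avoid a cycle

    df = pd.read_csv(path, parse_dates=["timestamp"])
    if len(df) < 2:
        raise ValueError("epoch CSV must contain at least two epochs")
    subject = str(df["subject_id"].iloc[0])
    deltas = df["timestamp"].diff().dropna().dt.total_seconds().to_numpy()
    step = deltas[0]
    if not np.allclose(deltas, step):
        raise ValueError("non-uniform epoch spacing in epoch CSV")
    a = [df[c].to_numpy(dtype=np.int64) for c in ("axis1", "axis2", "axis3")]
    return EpochSeries(
        subject_id=subject,
        start_time=df["timestamp"].iloc[0],
        epoch_seconds=int(step),
        counts_axis1=a[0],
        counts_axis2=a[1],
        counts_axis3=a[2],
    )


def read_minute_csv(path) -> pd.DataFrame:
    """Read pre-aggregated minute data (subject_id, timestamp, axis1, vm)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"subject_id", "timestamp", "axis1", "vm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"minute CSV missing columns: {sorted(missing)}")
    return df
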