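"""Synthetic accelerometer cohorts with known ground-truth variance structure.

The generator emulates a free-living monitoring study in which adults wear a
hip accelerometer continuously for three weeks: 10-second epoch counts on
three axes, a nightly device-off block plus occasional daytime removals, and
day-to-day behavioural variation with a known decomposition into
between-subject and within-subject (day-level) variance.  Because the true
variance components are known by construction, every downstream estimator
(non-wear detection, daily reduction, ICC/SEM/limits-of-agreement, mixed
models) can be tested for parameter recovery without any external data.

Generation happens in two stages:

* :func:`simulate_day_table` draws the *day-level* ground truth — wear
  minutes and daily outcome totals following linear mixed generating models
  (random subject intercept, weekend shift, wear-time slope, Normal day
  residual).
* :func:`simulate_cohort` expands each day into a minute-level intensity
  sequence (geometric bout lengths), draws per-minute counts inside the
  generating intensity band, inserts the non-wear blocks as all-zero
  stretches of >= 60 minutes, and splits minutes into 10-s epochs whose
  counts sum back to the minute count.

The day totals SED + LPA + MVPA must equal wear minutes exactly (intensity
classification partitions worn time), so the three behavioural outcomes
cannot all follow independent generating equations.  SED and MVPA (and CPM,
VM CPM, wear) follow their configured models exactly; LPA closes the budget
(``lpa = wear - sed - mvpa``), which induces an LPA wear-slope of
``1 - sed_wear_slope - mvpa_wear_slope`` — matching the pattern seen in real
hip-accelerometer data where light activity absorbs the remainder of worn
time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reduction import DEFAULT_CUTS, CutPointSet

logger = logging.getLogger(__name__)

OUTCOMES = ("cpm", "sed", "lpa", "mvpa")

# Daily means on the valid-day scale (minutes/day for behaviours, counts/min
# for cpm) and variance components (daily scale, outcome units squared).
DEFAULT_OUTCOME_MEANS = {"cpm": 486.0, "sed": 564.0, "lpa": 183.0, "mvpa": 66.0}
DEFAULT_SIGMA2_BETWEEN = {"cpm": 22600.0, "sed": 1500.0, "lpa": 2900.0, "mvpa": 230.0}
DEFAULT_SIGMA2_WITHIN = {"cpm": 50300.0, "sed": 2500.0, "lpa": 2300.0, "mvpa": 480.0}
# Additive shift applied on weekend days (weekday - weekend contrasts are
# therefore the negated values: activity higher, sedentary lower on weekdays).
DEFAULT_WEEKEND_EFFECT = {"cpm": -78.4, "sed": 18.2, "lpa": -6.9, "mvpa": -11.3}

# Mean within-band count level (cpm) assigned to minutes of each intensity
# state, and the admissible range each level may be moved within to realise a
# day's target CPM.  The light-activity level is the primary free knob.
STATE_LEVEL_DEFAULTS = {"sed": 30.0, "lpa": 900.0, "mpa": 2800.0, "vpa": 6500.0}
STATE_LEVEL_BOUNDS = {
    "sed": (5.0, 95.0),
    "lpa": (100.0, 2019.0),
    "mpa": (2020.0, 5998.0),
    "vpa": (5999.0, 12000.0),
}
STATE_BOUT_MEAN = {"sed": 20.0, "lpa": 8.0, "mpa": 5.0, "vpa": 2.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic monitoring study.

    Defaults describe the reference study conditions: 87 adults wearing the
    device for 21 consecutive days, ~800 worn minutes on a typical day with a
    30% chance of a partial-wear day, a strong positive wear-time slope for
    sedentary minutes, weekday > weekend activity, and variance components
    giving single-day ICCs of roughly 0.2-0.55 across outcomes.
    """

    n_subjects: int = 87
    n_days: int = 21
    epoch_seconds: int = 10
    start_date: str = "2014-03-31"  # a Monday in the study season

    mean_wear_minutes: float = 800.0
    wear_sd_between: float = 40.0
    wear_sd_within: float = 90.0
    wear_sd_week: float = 30.0
    #: probability that a day is a partial-wear day (device worn only part of
    #: the day), with wear drawn uniformly on ``low_wear_range``.
    low_wear_day_prob: float = 0.30
    low_wear_range: tuple = (300.0, 590.0)

    outcome_means: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MEANS))
    sigma2_between: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA2_BETWEEN))
    sigma2_within: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA2_WITHIN))
    weekend_effect: dict = field(default_factory=lambda: dict(DEFAULT_WEEKEND_EFFECT))

    sed_wear_slope: float = 0.709
    mvpa_wear_slope: float = 0.047
    #: correlation between the CPM and MVPA shocks (between and within), so
    #: that low-activity days are also low-intensity days.
    cpm_mvpa_corr: float = 0.6
    #: fraction of MVPA minutes spent vigorous (vigorous time is low in
    #: free-living adults).
    vpa_fraction: float = 0.02

    nonwear_bout_rate: float = 1.0
    axis2_fraction: float = 1.2
    axis3_fraction: float = 0.9
    seed: int = 0

    @property
    def vm_ratio(self) -> float:
        """Ratio of vector-magnitude to vertical-axis counts implied by the
        fixed axis proportions (sqrt(1 + f2^2 + f3^2) ~ 1.80)."""
        return float(np.sqrt(1.0 + self.axis2_fraction**2 + self.axis3_fraction**2))

    def validate(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 < self.mean_wear_minutes <= 1440):
            raise ValueError("mean_wear_minutes must lie in (0, 1440]")
        if self.epoch_seconds <= 0 or 60 % self.epoch_seconds != 0:
            raise ValueError("epoch_seconds must divide 60")
        for name, d in (("sigma2_between", self.sigma2_between), ("sigma2_within", self.sigma2_within)):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{name}[{k}] must be >= 0")
        if any(o not in self.outcome_means for o in OUTCOMES):
            raise ValueError(f"outcome_means must define all of {OUTCOMES}")
        behavioural = self.outcome_means["sed"] + self.outcome_means["lpa"] + self.outcome_means["mvpa"]
        if behavioural > 1440:
            raise ValueError(
                "implied daily SED+LPA+MVPA minutes exceed a 24 h day "
                f"({behavioural:.0f} min)"
            )
        if not (0 <= self.low_wear_day_prob < 1):
            raise ValueError("low_wear_day_prob must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["low_wear_range"] = list(self.low_wear_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.low_wear_range, list):
            cfg.low_wear_range = tuple(cfg.low_wear_range)
        return cfg

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a config from YAML or JSON mirroring the field names."""
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


@dataclass
class TrueParameters:
    """Generator ground truth echoed back for parameter-recovery tests."""

    config: SimulationConfig
    true_icc: dict
    subject_effects: pd.DataFrame  # realized random intercepts per subject

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "true_icc": self.true_icc,
            "subject_effects": self.subject_effects.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class EpochSeries:
    """One subject's contiguous epoch-level counts.

    ``vm`` is the per-epoch Euclidean norm of the three axis counts; it is
    computed at construction if not supplied.
    """

    subject_id: str
    start_time: pd.Timestamp
    epoch_seconds: int
    counts_axis1: np.ndarray
    counts_axis2: np.ndarray
    counts_axis3: np.ndarray
    vm: np.ndarray = None

    def __post_init__(self):
        if self.vm is None:
            self.vm = np.sqrt(
                self.counts_axis1.astype(float) ** 2
                + self.counts_axis2.astype(float) ** 2
                + self.counts_axis3.astype(float) ** 2
            )

    def __len__(self) -> int:
        return len(self.counts_axis1)


def true_single_day_icc(config: SimulationConfig, outcome: str) -> float:
    """Configured single-day ICC: sigma2_between / (sigma2_between + sigma2_within).

    For LPA — the closure outcome whose realized day totals are induced by
    the wear budget rather than drawn from its own equation — this is the
    *nominal* configured value, not the realized one.
    """
    if outcome not in config.sigma2_between or outcome not in config.sigma2_within:
        raise KeyError(f"unknown outcome: {outcome!r}")
    b = config.sigma2_between[outcome]
    w = config.sigma2_within[outcome]
    total = b + w
    if total == 0:
        raise ValueError("total variance is zero; ICC undefined")
    return b / total


# ---------------------------------------------------------------------------
# Stage 1: day-level ground truth
# ---------------------------------------------------------------------------

def simulate_day_table(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw the day-level latent study: wear minutes and daily outcome totals.

    Returns ``(day_table, TrueParameters)``.  The table has one row per
    subject-day with integer ``wear_minutes, sed_min, lpa_min, mpa_min,
    vpa_min, mvpa_min`` satisfying ``sed+lpa+mvpa == wear`` exactly, the
    day's target ``cpm`` and ``vm_cpm`` (clamped into the range achievable
    by within-band count levels), plus calendar metadata.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    S, D = config.n_subjects, config.n_days
    n_weeks = (D + 6) // 7
    mu = config.outcome_means
    s2b, s2w = config.sigma2_between, config.sigma2_within
    we = config.weekend_effect
    rho = config.cpm_mvpa_corr

    dates = pd.to_datetime(config.start_date) + pd.to_timedelta(np.arange(D), unit="D")
    weekend = np.asarray(dates.weekday >= 5)
    week_of_day = np.arange(D) // 7

    # subject-level effects (cpm and mvpa shocks correlated)
    zb = rng.standard_normal((S, 3))
    b_cpm = np.sqrt(s2b["cpm"]) * zb[:, 0]
    b_sed = np.sqrt(s2b["sed"]) * zb[:, 1]
    b_mvpa = np.sqrt(s2b["mvpa"]) * (rho * zb[:, 0] + np.sqrt(1 - rho**2) * zb[:, 2])
    b_wear = rng.normal(0.0, config.wear_sd_between, S)
    wk_wear = rng.normal(0.0, config.wear_sd_week, (S, n_weeks))

    # day-level shocks
    ze = rng.standard_normal((S, D, 3))
    e_cpm = np.sqrt(s2w["cpm"]) * ze[:, :, 0]
    e_sed = np.sqrt(s2w["sed"]) * ze[:, :, 1]
    e_mvpa = np.sqrt(s2w["mvpa"]) * (rho * ze[:, :, 0] + np.sqrt(1 - rho**2) * ze[:, :, 2])
    e_wear = rng.normal(0.0, config.wear_sd_within, (S, D))

    wear = (
        config.mean_wear_minutes
        + b_wear[:, None]
        + wk_wear[:, week_of_day]
        + e_wear
    )
    low = rng.random((S, D)) < config.low_wear_day_prob
    low_draw = rng.uniform(*config.low_wear_range, (S, D))
    wear = np.where(low, low_draw, wear)
    wear = np.clip(np.rint(wear), 60, 1350).astype(int)

    dw = wear - config.mean_wear_minutes
    wkd = weekend[None, :]

    mvpa = mu["mvpa"] + config.mvpa_wear_slope * dw + b_mvpa[:, None] + e_mvpa + we["mvpa"] * wkd
    mvpa = np.clip(np.rint(mvpa), 0, wear).astype(int)
    vpa = np.rint(config.vpa_fraction * mvpa).astype(int)
    mpa = mvpa - vpa

    sed = mu["sed"] + config.sed_wear_slope * dw + b_sed[:, None] + e_sed + we["sed"] * wkd
    sed = np.clip(np.rint(sed), 0, wear - mvpa).astype(int)
    lpa = wear - sed - mvpa  # closure; >= 0 by construction

    cpm = mu["cpm"] + b_cpm[:, None] + e_cpm + we["cpm"] * wkd
    lo_b = {k: v[0] for k, v in STATE_LEVEL_BOUNDS.items()}
    hi_b = {k: v[1] for k, v in STATE_LEVEL_BOUNDS.items()}
    cpm_lo = (lo_b["sed"] * sed + lo_b["lpa"] * lpa + lo_b["mpa"] * mpa + lo_b["vpa"] * vpa) / wear
    cpm_hi = (hi_b["sed"] * sed + hi_b["lpa"] * lpa + hi_b["mpa"] * mpa + hi_b["vpa"] * vpa) / wear
    cpm = np.clip(cpm, cpm_lo, cpm_hi)

    table = pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i:03d}" for i in range(S)], D),
            "day_index": np.tile(np.arange(1, D + 1), S),
            "date": np.tile(dates, S),
            "week_index": np.tile(week_of_day + 1, S),
            "weekend": np.tile(weekend, S),
            "low_wear": low.ravel(),
            "wear_minutes": wear.ravel(),
            "sed_min": sed.ravel(),
            "lpa_min": lpa.ravel(),
            "mpa_min": mpa.ravel(),
            "vpa_min": vpa.ravel(),
            "mvpa_min": mvpa.ravel(),
            "cpm": cpm.ravel(),
        }
    )
    table["vm_cpm"] = config.vm_ratio * table["cpm"]
    table["sed_pct"] = 100.0 * table["sed_min"] / table["wear_minutes"]
    table["lpa_pct"] = 100.0 * table["lpa_min"] / table["wear_minutes"]
    table["mvpa_pct"] = 100.0 * table["mvpa_min"] / table["wear_minutes"]

    effects = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(S)],
            "b_cpm": b_cpm,
            "b_sed": b_sed,
            "b_mvpa": b_mvpa,
            "b_wear": b_wear,
        }
    )
    truth = TrueParameters(
        config=config,
        true_icc={o: true_single_day_icc(config, o) for o in OUTCOMES},
        subject_effects=effects,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Stage 2: minute layout and epoch expansion
# ---------------------------------------------------------------------------

def _solve_state_levels(minutes: dict, target_total: float) -> dict:
    """Choose within-band mean count levels so the day's counts hit a target.

    Levels are adjusted one state at a time (light, moderate, sedentary,
    vigorous) within their band bounds until the implied total matches
    ``target_total``; the day-table CPM was clamped with the same bounds so
    a feasible solution exists up to rounding.
    """
    levels = dict(STATE_LEVEL_DEFAULTS)
    for st in ("lpa", "mpa", "sed", "vpa"):
        n = minutes[st]
        if n == 0:
            continue
        current = sum(minutes[s] * levels[s] for s in levels)
        lo, hi = STATE_LEVEL_BOUNDS[st]
        levels[st] = float(np.clip(levels[st] + (target_total - current) / n, lo, hi))
    return levels


def _nonwear_plan(rng: np.random.Generator, wear: int, rate: float):
    """Split a day's non-worn minutes into start/end blocks and daytime bouts.

    Every block is >= 60 minutes so the non-wear rule can recover it; the
    start block continues the previous night's device-off period across
    midnight.
    """
    nw = 1440 - wear
    day_bouts: list[int] = []
    if nw >= 120:
        k = rng.poisson(rate)
        for _ in range(k):
            L = 60 + int(rng.exponential(20.0))
            if nw - sum(day_bouts) - L >= 120:
                day_bouts.append(L)
        rest = nw - sum(day_bouts)
        if rest >= 120:
            start = 60 + int(rng.integers(0, rest - 119))
        else:  # pragma: no cover - rest >= 120 is guaranteed above
            start = rest
        end = rest - start
    else:
        start, end = nw, 0
    return start, end, day_bouts


def _state_sequence(rng: np.random.Generator, minutes: dict) -> np.ndarray:
    """Lay worn minutes down as shuffled bouts with geometric lengths."""
    pieces = []
    for si, st in enumerate(("sed", "lpa", "mpa", "vpa")):
        remaining = int(minutes[st])
        p = 1.0 / STATE_BOUT_MEAN[st]
        while remaining > 0:
            L = min(remaining, int(rng.geometric(p)))
            pieces.append((si, L))
            remaining -= L
    if not pieces:
        return np.empty(0, dtype=np.int8)
    order = rng.permutation(len(pieces))
    return np.concatenate([np.full(pieces[i][1], pieces[i][0], dtype=np.int8) for i in order])


def _draw_minute_counts(rng: np.random.Generator, states: np.ndarray, levels: dict) -> np.ndarray:
    """Per-minute vertical-axis counts inside each state's cpm band.

    Sedentary minutes are Poisson around the sedentary level, floored at 1
    count so genuinely worn time never mimics device-off; the active bands
    use truncated-Normal noise around their level.
    """
    counts = np.zeros(len(states), dtype=np.int64)
    specs = {
        0: ("sed", None),
        1: ("lpa", None),
        2: ("mpa", 350.0),
        3: ("vpa", 400.0),
    }
    for si, (st, sd) in specs.items():
        idx = np.flatnonzero(states == si)
        n = len(idx)
        if n == 0:
            continue
        lo, hi = STATE_LEVEL_BOUNDS[st]
        level = levels[st]
        if st == "sed":
            lo, hi = 1, 99  # minute counts may roam the whole band
            draw = np.clip(rng.poisson(level, n), lo, hi)
        else:
            if st == "lpa":
                sd = 0.12 * level + 10.0
            # shrink noise near the band edges so truncation cannot bias the
            # state's realised mean away from its level
            sd = min(sd, 0.8 * (level - lo) + 1.0, 0.8 * (hi - level) + 1.0)
            draw = np.clip(np.rint(rng.normal(level, sd, n)), lo, hi).astype(np.int64)
        # nudge toward the exact state total so the day's realised CPM
        # matches its generating value up to integer rounding
        delta = int(round(level * n)) - int(draw.sum())
        if delta:
            base, rem = divmod(abs(delta), n)
            adj = np.full(n, base, dtype=np.int64)
            adj[:rem] += 1
            draw = np.clip(draw + np.sign(delta) * adj, lo, hi)
        counts[idx] = draw
    return counts


def _layout_day(rng: np.random.Generator, row, rate: float) -> np.ndarray:
    """Minute-level vertical-axis counts for one subject-day (1440 values)."""
    wear = int(row.wear_minutes)
    minutes = {
        "sed": int(row.sed_min),
        "lpa": int(row.lpa_min),
        "mpa": int(row.mpa_min),
        "vpa": int(row.vpa_min),
    }
    start, end, day_bouts = _nonwear_plan(rng, wear, rate)
    states = _state_sequence(rng, minutes)
    levels = _solve_state_levels(minutes, float(row.cpm) * wear)
    counts_worn = _draw_minute_counts(rng, states, levels)

    day = np.zeros(1440, dtype=np.int64)
    if day_bouts and wear > 1:
        # insert device-off bouts between worn minutes
        positions = np.sort(rng.integers(1, wear, len(day_bouts)))
        segments = []
        prev = 0
        for pos, L in zip(positions, day_bouts):
            segments.append(counts_worn[prev:pos])
            segments.append(np.zeros(L, dtype=np.int64))
            prev = pos
        segments.append(counts_worn[prev:])
        middle = np.concatenate(segments)
    else:
        middle = counts_worn
    day[start : start + len(middle)] = middle

    # occasional short non-zero spike inside a long device-off block; the
    # detection rule's interruption tolerance absorbs it
    for blk_start, blk_len in ((0, start), (1440 - end, end)):
        if blk_len >= 90 and rng.random() < 0.15:
            pos = blk_start + int(rng.integers(15, blk_len - 17))
            n_spike = int(rng.integers(1, 3))
            day[pos : pos + n_spike] = rng.integers(10, 90, n_spike)
    return day


def _expand_axes(rng: np.random.Generator, a1_min: np.ndarray, config: SimulationConfig):
    """Minute counts for axes 2/3 and the epoch split for all three axes."""
    n = len(a1_min)
    f2 = rng.normal(config.axis2_fraction, 0.05, n)
    f3 = rng.normal(config.axis3_fraction, 0.05, n)
    a2_min = np.clip(np.rint(a1_min * f2), 0, None).astype(np.int64)
    a3_min = np.clip(np.rint(a1_min * f3), 0, None).astype(np.int64)

    per_min = 60 // config.epoch_seconds
    p = np.full(per_min, 1.0 / per_min)
    epochs = []
    for a in (a1_min, a2_min, a3_min):
        e = rng.multinomial(a, p)
        epochs.append(e.reshape(-1).astype(np.int64))
    return epochs


def simulate_cohort(config: SimulationConfig):
    """Generate a full cohort of epoch series plus ground truth.

    Returns ``(series_list, TrueParameters)`` with one
    :class:`EpochSeries` per subject spanning ``n_days`` calendar days from
    midnight of ``start_date``.  Identical config and seed give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    table, truth = simulate_day_table(config, rng)
    start_time = pd.to_datetime(config.start_date)

    series_list = []
    for sid, sub in table.groupby("subject_id", sort=True):
        sub = sub.sort_values("day_index")
        day_arrays = [_layout_day(rng, row, config.nonwear_bout_rate) for row in sub.itertuples()]
        a1_min = np.concatenate(day_arrays)
        e1, e2, e3 = _expand_axes(rng, a1_min, config)
        series_list.append(
            EpochSeries(
                subject_id=str(sid),
                start_time=start_time,
                epoch_seconds=config.epoch_seconds,
                counts_axis1=e1,
                counts_axis2=e2,
                counts_axis3=e3,
            )
        )
    return series_list, truth


# ---------------------------------------------------------------------------
# Disk interchange
# ---------------------------------------------------------------------------

def write_cohort(series_list, truth: TrueParameters, outdir) -> None:
    """Write per-subject epoch CSVs and the ground-truth JSON.

    Each CSV has columns ``subject_id, timestamp, axis1, axis2, axis3`` with
    one row per epoch (ISO 8601 timestamps); vector magnitude is derivable
    and not stored.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for es in series_list:
        ts = es.start_time + pd.to_timedelta(
            np.arange(len(es)) * es.epoch_seconds, unit="s"
        )
        df = pd.DataFrame(
            {
                "subject_id": es.subject_id,
                "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                "axis1": es.counts_axis1,
                "axis2": es.counts_axis2,
                "axis3": es.counts_axis3,
            }
        )
        df.to_csv(outdir / f"{es.subject_id}.csv", index=False)
    truth.to_json(outdir / "true_parameters.json")


def read_cohort(indir):
    """Read every per-subject epoch CSV in a directory."""
    from .reduction import read_epoch_csv

    paths = sorted(Path(indir).glob("S*.csv"))
    if not paths:
        raise FileNotFoundError(f"no epoch CSVs found under {indir}")
    return [read_epoch_csv(p) for p in paths]
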