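"""End-to-end orchestration: simulate -> reduce -> analyse -> report.

:func:`run_pipeline` executes the whole reliability analysis on either a
directory of epoch CSVs or a freshly simulated cohort and writes a
reproducible report bundle:

* ``wear_association.csv`` — wear-time slopes per outcome (random-intercept
  mixed models, >= 10 h days),
* ``daily_reliability.csv`` — single-day ICC and Spearman-Brown days-needed
  per outcome for each hour criterion,
* ``weekly_reliability.csv`` — week-by-week ICC/SEM/SEM%/LoA, crude and
  wear-adjusted, at the primary criteria,
* ``weekly_reliability_grid.csv`` — weekly ICC and SEM over the full
  hours x days criteria grid,
* ``bland_altman_<outcome>.csv`` / ``.svg`` — week-1-anchored agreement
  pairs and plots,
* ``manifest.json`` and a run log.

Identical configuration and seed give byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman, pair_weeks, plot_bland_altman
from .association import association_table, weekday_weekend_effect, weekweekend_variance_ratio
from .reduction import (
    DEFAULT_CUTS,
    OUTCOME_COLUMNS,
    CutPointSet,
    WearCriteria,
    cohort_to_minutes,
    detect_nonwear,
    filter_valid_days,
    summarize_days,
    summarize_weeks,
)
from .reliability import reliability_table, weekly_reliability_table
from .synthetic import SimulationConfig, read_cohort, simulate_cohort

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_dir: str | None = None  # epoch CSVs; None -> simulate
    output_dir: str = "accelrel_out"
    simulation: SimulationConfig | None = None
    hour_criteria: tuple = (8, 10, 12)
    day_criteria: tuple = (3, 4, 5)
    primary_hours: float = 10.0
    primary_days: int = 4
    cuts: CutPointSet = field(default_factory=lambda: DEFAULT_CUTS)
    icc_t: float = 0.80
    adjust_wear: bool = True
    seed: int = 0
    log_level: str = "INFO"
    plot_outcomes: tuple = ("cpm", "sed_min", "mvpa_min")

    def validate(self) -> None:
        if not self.hour_criteria or not self.day_criteria:
            raise ValueError("criteria grid must be non-empty")
        if not (0 < self.icc_t < 1):
            raise ValueError("icc_t must lie in (0, 1)")
        if self.input_dir is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def paper_scale_config(seed: int = 0) -> RunConfig:
    """Preset reproducing the reference study design: 87 subjects x 21 days."""
    return RunConfig(simulation=SimulationConfig(seed=seed), seed=seed)


def demo_config(seed: int = 1, n_subjects: int = 20) -> RunConfig:
    """Small demonstration run (20 subjects x 21 days by default)."""
    return RunConfig(simulation=SimulationConfig(n_subjects=n_subjects, seed=seed), seed=seed)


def _setup_logging(outdir: Path, level: str):
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("accelrel")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    root.addHandler(handler)
    return handler


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of the in-memory result tables keyed by file stem.
    Any stage failure raises with the stage named in the log.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir, config.log_level)
    results: dict = {}
    try:
        # --- stage: input ------------------------------------------------
        if config.input_dir is not None:
            logger.info("stage input: reading epoch CSVs from %s", config.input_dir)
            series_list = read_cohort(config.input_dir)
        else:
            logger.info(
                "stage simulate: %d subjects x %d days, seed %d",
                config.simulation.n_subjects, config.simulation.n_days, config.simulation.seed,
            )
            series_list, truth = simulate_cohort(config.simulation)
            truth.to_json(outdir / "true_parameters.json")

        # --- stage: reduce -----------------------------------------------
        logger.info("stage reduce: epoch -> minute -> day/week summaries")
        minutes = cohort_to_minutes(series_list)
        minutes = detect_nonwear(minutes)
        days = summarize_days(minutes, config.cuts)
        _write_csv(days, outdir / "days.csv")
        primary = WearCriteria(config.primary_hours, config.primary_days)
        valid_days, frac_days = filter_valid_days(days, primary)
        weeks, frac_weeks = summarize_weeks(days, primary)
        _write_csv(weeks, outdir / "weeks.csv")
        results["days"] = days
        results["weeks"] = weeks

        # --- stage: associations ------------------------------------------
        logger.info("stage associate: wear-time and day-type mixed models")
        assoc = association_table(valid_days, OUTCOME_COLUMNS)
        extra = []
        for outcome in OUTCOME_COLUMNS:
            fit = weekday_weekend_effect(valid_days, outcome)
            extra.append(
                {
                    "outcome": outcome,
                    "weekday_beta": fit.beta,
                    "weekday_ci_low": fit.ci_low,
                    "weekday_ci_high": fit.ci_high,
                    "weekday_p": fit.p_value,
                    "daytype_variance_ratio": weekweekend_variance_ratio(valid_days, outcome),
                }
            )
        assoc = assoc.merge(pd.DataFrame(extra), on="outcome")
        _write_csv(assoc, outdir / "wear_association.csv")
        results["wear_association"] = assoc

        # --- stage: daily reliability -------------------------------------
        logger.info("stage reliability: single-day ICC grid")
        daily = reliability_table(days, config.hour_criteria, icc_t=config.icc_t)
        daily_out = daily.assign(
            icc_s=daily["icc_s"].round(2), n_days_needed=daily["n_days_needed"].round(1)
        )
        _write_csv(daily_out, outdir / "daily_reliability.csv")
        results["daily_reliability"] = daily

        # --- stage: weekly reliability ------------------------------------
        logger.info("stage reliability: week-by-week tables")
        weekly_frames = [weekly_reliability_table(weeks, adjust=False, icc_t=config.icc_t)]
        if config.adjust_wear:
            weekly_frames.append(weekly_reliability_table(weeks, adjust=True, icc_t=config.icc_t))
        weekly = pd.concat(weekly_frames, ignore_index=True)
        weekly_out = weekly.assign(
            icc_s=weekly["icc_s"].round(2),
            sem=weekly["sem"].round(1),
            sem_pct=weekly["sem_pct"].round(1),
            loa=weekly["loa"].round(1),
        )
        _write_csv(weekly_out, outdir / "weekly_reliability.csv")
        results["weekly_reliability"] = weekly

        grid_rows = []
        for h in config.hour_criteria:
            for d in config.day_criteria:
                wk, frac = summarize_weeks(days, WearCriteria(h, d))
                try:
                    tab = weekly_reliability_table(wk, adjust=False, icc_t=config.icc_t)
                except Exception as err:  # degenerate criteria cells
                    logger.warning("weekly grid cell >=%sh/>=%sd failed: %s", h, d, err)
                    continue
                tab.insert(1, "min_hours", h)
                tab.insert(2, "min_days", d)
                tab.insert(3, "retained_week_frac", frac)
                grid_rows.append(tab)
        grid = pd.concat(grid_rows, ignore_index=True)
        _write_csv(
            grid.assign(icc_s=grid["icc_s"].round(2), sem=grid["sem"].round(1)),
            outdir / "weekly_reliability_grid.csv",
        )
        results["weekly_reliability_grid"] = grid

        # --- stage: agreement ---------------------------------------------
        logger.info("stage agree: Bland-Altman week-by-week agreement")
        crude = weekly_frames[0].set_index("outcome")
        for outcome in config.plot_outcomes:
            pairs = pair_weeks(weeks, outcome)
            if len(pairs) < 3:
                logger.warning("too few pairs for %s agreement; skipped", outcome)
                continue
            ba = bland_altman(pairs, crude.loc[outcome, "sem"])
            _write_csv(pairs, outdir / f"bland_altman_{outcome}.csv")
            plot_bland_altman(ba, outcome, outdir / f"bland_altman_{outcome}.svg")
            results[f"bland_altman_{outcome}"] = ba

        # --- manifest ------------------------------------------------------
        manifest = {
            "package_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": _config_dict(config),
            "retained_day_fraction_primary": frac_days,
            "retained_week_fraction_primary": frac_weeks,
        }
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True).encode()
        ).hexdigest()
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("pipeline complete: %s", outdir)
        return results
    finally:
        logging.getLogger("accelrel").removeHandler(handler)
        handler.close()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cuts"] = dataclasses.asdict(config.cuts)
    if config.simulation is not None:
        d["simulation"] = config.simulation.to_dict()
    for key in ("hour_criteria", "day_criteria", "plot_outcomes"):
        d[key] = list(d[key])
    return d


# ---------------------------------------------------------------------------
# Test fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int = 0, outdir=None):
    """Deterministic fixture set: a tiny cohort plus hand-checkable sequences.

    Returns ``(series_list, truth, sequences)`` where ``sequences`` maps a
    name to ``(minute_counts, expected_nonwear_minutes)`` for unit tests of
    the non-wear rule.  When ``outdir`` is given, the cohort is written as
    epoch CSVs and the sequences as a JSON file.
    """
    cfg = SimulationConfig(n_subjects=5, n_days=21, seed=seed)
    series_list, truth = simulate_cohort(cfg)

    act = [50] * 10  # bounding activity
    sequences = {
        "59_zeros": (act + [0] * 59 + act, 0),
        "60_zeros": (act + [0] * 60 + act, 60),
        "70_zeros": (act + [0] * 70 + act, 70),
        "62min_2min_interruption": (act + [0] * 30 + [40, 40] + [0] * 30 + act, 62),
        "63min_3min_interruption": (act + [0] * 30 + [40, 40, 40] + [0] * 30 + act, 0),
    }
    if outdir is not None:
        outdir = Path(outdir)
        from .synthetic import write_cohort

        write_cohort(series_list, truth, outdir)
        payload = {
            name: {"counts": counts, "expected_nonwear_minutes": exp}
            for name, (counts, exp) in sequences.items()
        }
        (outdir / "nonwear_sequences.json").write_text(json.dumps(payload, indent=2))
    return series_list, truth, sequences
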