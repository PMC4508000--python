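"""Week-by-week Bland-Altman agreement analysis.

For each subject with valid adjacent weeks, the difference between two weekly
means is plotted against their average, anchored on week 1 (week 1 vs week 2
and week 1 vs week 3 pairs).  The 95% limits of agreement are derived from
the variance-component SEM of the weekly means (LoA = SEM * sqrt(2) * 1.96)
rather than from the pair SD, so the same residual-variance error term
underlies both the ICC/SEM table and the agreement plot.  A simple
absolute-residual regression of |difference| on the pair mean provides a
heteroscedasticity diagnostic (variability growing with activity level).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .reliability import ReliabilityEstimate, loa_from_sem

logger = logging.getLogger(__name__)

PAIR_LABELS = ("1v2", "1v3")


@dataclass
class BlandAltmanResult:
    """Pairs, bias, LoA half-width and heteroscedasticity diagnostics."""

    pairs: pd.DataFrame  # columns subject_id, pair_label, mean, diff
    mean_diff: float
    loa_half_width: float
    n_pairs_by_label: dict
    hetero_slope: float = float("nan")
    hetero_p: float = float("nan")

    @property
    def loa_lines(self):
        return (self.mean_diff - self.loa_half_width, self.mean_diff + self.loa_half_width)


def pair_weeks(weeks: pd.DataFrame, outcome: str, include_2v3: bool = False) -> pd.DataFrame:
    """Week-1-anchored (mean, difference) pairs for one outcome.

    For each subject, emits week1-week2 and week1-week3 pairs whenever both
    member weeks are present; subjects lacking a valid week 1 contribute no
    pairs.  ``include_2v3`` additionally emits week2-week3 pairs.
    """
    wide = weeks.pivot_table(index="subject_id", columns="week_index", values=outcome)
    combos = [(1, 2, "1v2"), (1, 3, "1v3")]
    if include_2v3:
        combos.append((2, 3, "2v3"))
    rows = []
    for a, b, label in combos:
        if a not in wide.columns or b not in wide.columns:
            continue
        sub = wide[[a, b]].dropna()
        for sid, (va, vb) in sub.iterrows():
            rows.append(
                {
                    "subject_id": sid,
                    "pair_label": label,
                    "mean": (va + vb) / 2.0,
                    "diff": va - vb,
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "pair_label", "mean", "diff"])


def heteroscedasticity_check(pairs: pd.DataFrame):
    """Regress |difference| on the pair mean.

    Returns ``(slope, two_sided_p)``; a slope significantly different from
    zero at alpha = .05 indicates variability that grows (or shrinks) with
    the measured level.  Requires >= 10 pairs and non-degenerate means.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs for the heteroscedasticity check")
    x = pairs["mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("pair means are constant; slope not identified")
    y = np.abs(pairs["diff"].to_numpy(dtype=float))
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.pvalues[1])


def bland_altman(pairs: pd.DataFrame, sem_source) -> BlandAltmanResult:
    """Bland-Altman summary with LoA taken from a variance-component SEM.

    ``sem_source`` is either a :class:`ReliabilityEstimate` or a plain SEM
    value.  The mean difference is computed over all pairs; the LoA
    half-width is ``SEM * sqrt(2) * 1.96``.  The heteroscedasticity
    diagnostic is attached when at least 10 pairs are available.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    sem = sem_source.sem if isinstance(sem_source, ReliabilityEstimate) else float(sem_source)
    counts = pairs["pair_label"].value_counts().to_dict()
    result = BlandAltmanResult(
        pairs=pairs.reset_index(drop=True),
        mean_diff=float(pairs["diff"].mean()),
        loa_half_width=loa_from_sem(sem),
        n_pairs_by_label=counts,
    )
    if len(pairs) >= 10 and np.ptp(pairs["mean"].to_numpy()) > 0:
        result.hetero_slope, result.hetero_p = heteroscedasticity_check(pairs)
    return result


def plot_bland_altman(result: BlandAltmanResult, outcome: str, path=None):
    """Scatter of week differences vs means with dotted LoA reference lines.

    Week1-week2 pairs are filled dots, week1-week3 pairs open squares.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    markers = {"1v2": dict(marker="o", color="black"),
               "1v3": dict(marker="s", facecolors="none", edgecolors="black"),
               "2v3": dict(marker="^", color="grey")}
    for label, grp in result.pairs.groupby("pair_label"):
        style = markers.get(label, dict(marker="x", color="grey"))
        ax.scatter(grp["mean"], grp["diff"], s=18, label=label, **style)
    lo, hi = result.loa_lines
    for yline in (result.mean_diff, lo, hi):
        ax.axhline(yline, linestyle=":", color="black", linewidth=1)
    ax.set_xlabel(f"mean of two weeks ({outcome})")
    ax.set_ylabel("difference between weeks")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
    return fig
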