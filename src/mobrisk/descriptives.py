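"""Cohort-comparison statistics and panel bookkeeping.

Two-site comparison conventions used throughout:

* 2x2 tables: Pearson chi-square **with Yates continuity correction**;
  larger tables: uncorrected Pearson chi-square.
* Odds ratios are oriented as the second group's odds over the first's.
* t tests use Welch's unequal-variance form, signed second group minus
  first.
* Cramer's V is reported in two conventions: the standard
  sqrt(chi2 / (n * min(r-1, c-1))) and a df-normalised
  sqrt(chi2 / (n * (r-1)(c-1))); they coincide for 2x2 tables.

The chi-square machinery delegates to scipy.stats; effect sizes are
direct formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


def _as_table(tbl) -> np.ndarray:
    t = np.asarray(tbl, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be >= 0")
    return t


def odds_ratio_2x2(tbl) -> tuple[float, bool]:
    """Odds ratio of a 2x2 table: odds in column 2 over odds in column 1.

    Rows = characteristic yes/no, columns = groups.  Returns
    ``(or, corrected)``; a zero cell triggers the Haldane-Anscombe 0.5
    correction and sets the flag.
    """
    t = _as_table(tbl)
    if t.shape != (2, 2):
        raise ValueError("odds ratio needs a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be > 0")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    return float((b / d) / (a / c)), corrected


def chi_square(tbl, yates: bool | None = None) -> tuple[float, int]:
    """Pearson chi-square statistic and df.

    2x2 tables use the Yates continuity correction by default; larger
    tables are uncorrected.  Pass ``yates`` to override.  Expected counts
    below 1 produce a warning, not an error.
    """
    t = _as_table(tbl)
    correction = (t.shape == (2, 2)) if yates is None else yates
    res = stats.chi2_contingency(t, correction=correction)
    expected = res.expected_freq
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; chi-square may be unreliable", stacklevel=2)
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return float(res.statistic), int(df)


def welch_t(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float]:
    """Welch's t (second group minus first) and Welch-Satterthwaite df."""
    v1 = g1.sd**2 / g1.n
    v2 = g2.sd**2 / g2.n
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups; t undefined")
    t = (g2.mean - g1.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(t), float(df)


def cohens_d(g1: GroupSummary, g2: GroupSummary) -> float:
    """Cohen's d with the pooled SD, signed second group minus first."""
    pooled = np.sqrt(
        ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    )
    if pooled == 0:
        return 0.0
    return float((g2.mean - g1.mean) / pooled)


def cramers_v(tbl, yates: bool | None = None) -> dict[str, float]:
    """Cramer's V in both conventions (they coincide for 2x2 tables).

    ``standard``: sqrt(chi2 / (n * min(r-1, c-1)));
    ``df_normalized``: sqrt(chi2 / (n * (r-1)(c-1))).
    """
    t = _as_table(tbl)
    chi2, df = chi_square(t, yates=yates)
    n = t.sum()
    r, c = t.shape
    return {
        "standard": float(np.sqrt(chi2 / (n * min(r - 1, c - 1)))),
        "df_normalized": float(np.sqrt(chi2 / (n * df))),
    }


def panel_counts(
    daily: pd.DataFrame,
    event_panel: pd.DataFrame,
    ideation_panel: pd.DataFrame,
    merged_events: pd.DataFrame,
    n_participants: int | None = None,
    n_weeks: int | None = None,
) -> dict:
    """Bookkeeping report: usable weeks, events, availability fractions."""
    report = {
        "event_panel_weeks": int(len(event_panel)),
        "ideation_panel_weeks": int(len(ideation_panel)),
        "merged_event_count": int(len(merged_events)),
        "unique_event_participants": int(merged_events["participant_id"].nunique())
        if len(merged_events)
        else 0,
        "event_weeks_with_event": int((event_panel["outcome"] == 1).sum())
        if len(event_panel)
        else 0,
        "ideation_weeks_flagged": int((ideation_panel["outcome"] == 1).sum())
        if len(ideation_panel)
        else 0,
    }
    if n_participants and n_weeks:
        total_days = n_participants * n_weeks * 7
        report["gps_day_fraction"] = float(len(daily) / total_days)
    report["n_gps_days"] = int(len(daily))
    return report
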