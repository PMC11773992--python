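"""Wednesday-aligned weekly panels with within/between decomposition.

Daily mobility features are averaged into weeks running Wednesday 00:00 to
Tuesday 24:00 local time (weekly surveys go out on Wednesdays); weeks with
fewer than 3 GPS days contribute no feature values.  Each feature is then
decomposed into a person-mean-centred *within* term (scaled by the pooled
SD of centred values, so a unit is "1 SD above one's own mean") and a
z-scored person-mean *between* term.  Panels pair the outcome in week T
with feature terms from week T-L.

Suicidal events are merged before weekly flagging: an emergency-department
visit or hospitalization within 7 days after an attempt by the same
participant counts as the same event as the attempt.  Clinically
meaningful ideation on a responded survey means ideation frequency >= 4
(1-5 scale) or an endorsed plan; non-responded weeks are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import EVENT_TYPES, _ATTEMPT_TYPES

FEATURES = ("homestay", "entropy", "distance")

_DAILY_COLS = {"homestay": "homestay_h", "entropy": "entropy_nats", "distance": "distance_km"}

MERGE_WINDOW_DAYS = 7
MIN_GPS_DAYS = 3


def week0_wednesday(enrollment_date) -> pd.Timestamp:
    """The Wednesday on or before the enrollment date (start of week 0)."""
    d = pd.Timestamp(enrollment_date)
    return (d - pd.Timedelta(days=int((d.dayofweek - 2) % 7))).normalize()


def aggregate_weekly(
    daily: pd.DataFrame, enrollment: pd.Series | dict, n_weeks: int | None = None
) -> pd.DataFrame:
    """Average daily features into Wednesday-to-Tuesday weeks.

    Parameters
    ----------
    daily
        Output of :func:`mobrisk.features.compute_daily_features`.
    enrollment
        Mapping participant_id -> enrollment date.
    n_weeks
        Optional study length; weeks outside [0, n_weeks) are dropped with
        a warning.  When omitted, each participant's observed range is kept.

    Weeks with fewer than ``MIN_GPS_DAYS`` GPS days keep their row but have
    feature values set to NaN (the standard sparse-week exclusion rule).
    """
    if isinstance(enrollment, dict):
        enrollment = pd.Series(enrollment)
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    w0 = df["participant_id"].map(lambda p: week0_wednesday(enrollment.loc[p]))
    df["week_index"] = ((df["date"] - w0).dt.days // 7).astype(int)
    if (df["week_index"] < 0).any():
        import warnings

        n_bad = int((df["week_index"] < 0).sum())
        warnings.warn(f"dropping {n_bad} daily rows before enrollment week", stacklevel=2)
        df = df[df["week_index"] >= 0]
    if n_weeks is not None and (df["week_index"] >= n_weeks).any():
        import warnings

        n_bad = int((df["week_index"] >= n_weeks).sum())
        warnings.warn(f"dropping {n_bad} daily rows beyond the study window", stacklevel=2)
        df = df[df["week_index"] < n_weeks]
    grouped = df.groupby(["participant_id", "week_index"], sort=True)
    wk = grouped.agg(
        mean_homestay=("homestay_h", "mean"),
        mean_entropy=("entropy_nats", "mean"),
        mean_distance=("distance_km", "mean"),
        n_gps_days=("date", "nunique"),
    ).reset_index()
    wk["week_start"] = [
        week0_wednesday(enrollment.loc[p]) + pd.Timedelta(weeks=int(t))
        for p, t in zip(wk["participant_id"], wk["week_index"])
    ]
    low = wk["n_gps_days"] < MIN_GPS_DAYS
    wk.loc[low, ["mean_homestay", "mean_entropy", "mean_distance"]] = np.nan
    return wk[
        ["participant_id", "week_index", "week_start", "mean_homestay", "mean_entropy", "mean_distance", "n_gps_days"]
    ]


def merge_events(events: pd.DataFrame) -> pd.DataFrame:
    """Fold care contacts into the attempts they follow.

    An ED visit or hospitalization within ``MERGE_WINDOW_DAYS`` days *after*
    an attempt (actual/aborted/interrupted) by the same participant is
    merged into that attempt (the merged event keeps the attempt's date and
    type).  Attempts never merge with each other.  Idempotent.
    """
    if len(events) == 0:
        return events.copy().assign(n_merged=pd.Series(dtype=int))
    ev = events.copy()
    unknown = ~ev["event_type"].isin(EVENT_TYPES)
    if unknown.any():
        bad = sorted(ev.loc[unknown, "event_type"].unique())
        raise ValueError(f"unknown event_type {bad}; allowed: {list(EVENT_TYPES)}")
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev = ev.sort_values(["participant_id", "event_date"], kind="stable").reset_index(drop=True)
    is_attempt = ev["event_type"].isin(_ATTEMPT_TYPES).to_numpy()
    keep = np.ones(len(ev), dtype=bool)
    n_merged = np.zeros(len(ev), dtype=int)
    for pid, grp in ev.groupby("participant_id", sort=False):
        idx = grp.index.to_numpy()
        att = idx[is_attempt[idx]]
        for i in idx[~is_attempt[idx]]:
            d = ev.at[i, "event_date"]
            prior = [
                j
                for j in att
                if 0 <= (d - ev.at[j, "event_date"]).days <= MERGE_WINDOW_DAYS
            ]
            if prior:
                # absorb into the nearest preceding attempt
                j = max(prior, key=lambda j: ev.at[j, "event_date"])
                keep[i] = False
                n_merged[j] += 1
    out = ev[keep].copy()
    out["n_merged"] = n_merged[keep]
    return out.reset_index(drop=True)


def flag_ideation(esm: pd.DataFrame) -> pd.Series:
    """Clinically meaningful ideation flag per survey row.

    1 if responded and (ideation >= 4 or plan == yes); 0 if responded and
    neither; NA if not responded.  Ideation outside 1-5 on a responded row
    is a validation error.
    """
    responded = esm["responded"].astype(int) == 1
    ideation = pd.to_numeric(esm["ideation_1to5"], errors="coerce")
    bad = responded & (~ideation.between(1, 5) | ideation.isna())
    if bad.any():
        raise ValueError(
            f"ideation_1to5 outside 1-5 on responded rows at index {list(esm.index[bad])[:5]}"
        )
    plan_yes = esm["plan_yn"].astype(str).str.strip().str.lower() == "yes"
    flag = ((ideation >= 4) | plan_yes).astype(float)
    flag[~responded] = np.nan
    return flag


def weekly_outcomes(
    esm: pd.DataFrame, events: pd.DataFrame, enrollment: pd.Series | dict
) -> pd.DataFrame:
    """Per participant-week event and ideation flags.

    Events are merged first; an event week is the Wednesday-aligned week
    containing the (merged) event date.  A survey dated D reports on the
    week *ending* the day before D (surveys go out the Wednesday after the
    recalled week).
    """
    if isinstance(enrollment, dict):
        enrollment = pd.Series(enrollment)
    merged = merge_events(events)
    rows = {}

    def _week_of(pid, date):
        return int((pd.Timestamp(date) - week0_wednesday(enrollment.loc[pid])).days // 7)

    for _, r in merged.iterrows():
        pid = r["participant_id"]
        t = _week_of(pid, r["event_date"])
        key = (pid, t)
        rec = rows.setdefault(key, {"event_flag": 0, "event_ids": [], "ideation_flag": np.nan, "responded": 0})
        rec["event_flag"] = 1
        rec["event_ids"].append(str(r.get("event_type", "event")) + ":" + str(r["event_date"].date()))
    if len(esm):
        flags = flag_ideation(esm)
        for (_, r), f in zip(esm.iterrows(), flags):
            pid = r["participant_id"]
            t = _week_of(pid, pd.Timestamp(r["survey_date"]) - pd.Timedelta(days=1))
            key = (pid, t)
            rec = rows.setdefault(key, {"event_flag": 0, "event_ids": [], "ideation_flag": np.nan, "responded": 0})
            rec["responded"] = int(r["responded"])
            rec["ideation_flag"] = f
    out = pd.DataFrame(
        [
            {"participant_id": pid, "week_index": t, **rec}
            for (pid, t), rec in sorted(rows.items(), key=lambda kv: (str(kv[0][0]), kv[0][1]))
        ],
        columns=["participant_id", "week_index", "event_flag", "event_ids", "ideation_flag", "responded"],
    )
    return out


def decompose(weekly: pd.DataFrame) -> pd.DataFrame:
    """Within/between standardized terms for each feature.

    within = (x_it - mean_i) / SD of *all* centred values (pooled across
    the sample); between = (mean_i - grand mean of person means) / SD of
    person means.  Participants with fewer than 2 feature-bearing weeks get
    missing within terms (their single week cannot deviate from its own
    mean in any meaningful way).
    """
    out = weekly.copy()
    for feat in FEATURES:
        col = f"mean_{feat}"
        usable = out[col].notna()
        counts = out.loc[usable].groupby("participant_id")[col].transform("count")
        pm = out.loc[usable].groupby("participant_id")[col].transform("mean")
        centered = out.loc[usable, col] - pm
        enough = counts >= 2
        sd_w = centered[enough].std(ddof=1)
        person_means = out.loc[usable].groupby("participant_id")[col].mean()
        sd_b = person_means.std(ddof=1)
        within = pd.Series(np.nan, index=out.index)
        within[centered.index[enough]] = centered[enough] / (sd_w if sd_w and sd_w > 0 else 1.0)
        between = pd.Series(np.nan, index=out.index)
        bet_vals = (pm - person_means.mean()) / (sd_b if sd_b and sd_b > 0 else 1.0)
        between[pm.index] = bet_vals
        out[f"{feat}_within"] = within
        out[f"{feat}_between"] = between
    return out


def build_panel(
    weekly: pd.DataFrame,
    outcomes: pd.DataFrame,
    lag: int = 1,
    outcome_kind: str = "events",
) -> pd.DataFrame:
    """Pair outcome at week T with standardized features from week T-lag.

    ``weekly`` must already carry the decomposition columns.  Rows lacking
    the lagged within terms are dropped; for ``outcome_kind='ideation'``
    rows without a survey response are dropped too.  Weeks with no outcome
    record count as outcome 0 for events (events are exhaustively
    ascertained) but missing for ideation (survey-dependent).
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if outcome_kind not in ("events", "ideation"):
        raise ValueError("outcome_kind must be 'events' or 'ideation'")
    feat_cols = [f"{f}_within" for f in FEATURES] + [f"{f}_between" for f in FEATURES]
    wk = weekly[["participant_id", "week_index"] + feat_cols].copy()
    lagged = wk.copy()
    lagged["week_index"] = lagged["week_index"] + lag
    rows = lagged.merge(
        outcomes[["participant_id", "week_index", "event_flag", "ideation_flag", "responded"]],
        on=["participant_id", "week_index"],
        how="left",
    )
    max_week = weekly.groupby("participant_id")["week_index"].max()
    rows = rows[rows["week_index"] <= rows["participant_id"].map(max_week)]
    rows = rows.dropna(subset=[f"{f}_within" for f in FEATURES])
    if outcome_kind == "events":
        rows["outcome"] = rows["event_flag"].fillna(0).astype(int)
    else:
        rows = rows[rows["ideation_flag"].notna()]
        rows["outcome"] = rows["ideation_flag"].astype(int)
    rows["weeks_since_baseline"] = rows["week_index"]
    rows["lag"] = lag
    cols = ["participant_id", "week_index", "outcome"] + feat_cols + ["weeks_since_baseline", "lag"]
    return rows[cols].reset_index(drop=True)


def build_reversed_panel(weekly: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Bidirectional check: event at T-1 paired with feature terms at T.

    Used with linear models of each within-person feature as the outcome.
    """
    feat_cols = [f"{f}_within" for f in FEATURES]
    wk = weekly[["participant_id", "week_index"] + feat_cols].dropna(subset=feat_cols).copy()
    ev = outcomes[["participant_id", "week_index", "event_flag"]].copy()
    ev["week_index"] = ev["week_index"] + 1
    out = wk.merge(ev, on=["participant_id", "week_index"], how="left")
    out["event_prev_week"] = out["event_flag"].fillna(0).astype(int)
    out["weeks_since_baseline"] = out["week_index"]
    return out.drop(columns=["event_flag"]).reset_index(drop=True)


def panel_to_frame(panel: pd.DataFrame) -> pd.DataFrame:
    """Panel in the on-disk column layout (weekly_panel.csv)."""
    renames = {
        "homestay_within": "hw_within",
        "entropy_within": "en_within",
        "distance_within": "di_within",
        "homestay_between": "hw_between",
        "entropy_between": "en_between",
        "distance_between": "di_between",
    }
    return panel.rename(columns=renames)
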